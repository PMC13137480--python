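# Skeleton templates for the two structure-defined subclasses.
#
# 2,5-diketopiperazine: the piperazine-2,5-dione six-ring with both ring
# carbonyls; ring substituents (side chains, N-substituents) are
# unrestricted.  The pattern is chirality-free.
#
# emericellamide: the macrocyclic depsipeptide core, i.e. the lactone of
# N-(beta-hydroxyacyl)glycyl-L-valyl-L-leucyl-L-alanyl-L-alanine, with the
# two hydrocarbyl attachment points of the beta-hydroxyacyl unit as
# carbon wildcards.  Stereocentres are part of the pattern and matching is
# chirality-sensitive; molecules with the corresponding centres unassigned
# do not match.

skeletons:
  - name: 2,5-diketopiperazine
    required_class: dipeptide
    smarts: "C1(=O)CNC(=O)CN1"
    use_chirality: false
  - name: emericellamide
    required_class: pentapeptide
    smarts: "O=C1CNC(=O)[C@H]([#6])[C@@H]([#6])OC(=O)[C@H](C)NC(=O)[C@H](C)NC(=O)[C@H](CC(C)C)NC(=O)[C@H](C(C)C)N1"
    use_chirality: true
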