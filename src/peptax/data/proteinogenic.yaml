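# Residue templates for the 23 proteinogenic amino acids.
#
# Each template is the free L-amino acid written as SMILES with atom-map
# markers for the "flex" positions, i.e. the atoms that are matched by the
# amino-residue / carboxy-residue predicates instead of literally:
#
#   :1  backbone (or ring) amino nitrogen        -> flex amino
#   :2  backbone carboxy carbon                  -> flex carboxy
#   :3  side-chain carboxy carbon (Asp/Glu)      -> flex carboxy, but the
#       single-bonded partner must not be an NH2 (an NH2 there would make
#       the residue asparagine/glutamine instead); NH with one hydrogen
#       (isopeptide bond) is allowed
#   :4  side-chain amino nitrogen (Lys)          -> flex amino
#
# All other atoms must match literally: element, formal charge, hydrogen
# count, heavy-atom degree, bonds, and the CIP descriptor where one is set
# in the template.  The oxygens written on a flex carboxy carbon are
# placeholders and are dropped when the template is compiled.
#
# `variants` are alternative drawings of the same residue (tautomers of the
# arginine guanidine and histidine imidazole, plus the protonated
# guanidinium so that arginium-type cations are still recognised as
# arginine residues).
#
# `exclusions` name extra post-match checks; `no_n_formyl` rejects a match
# whose amino nitrogen carries a formyl group (that residue is
# N-formylmethionine, not methionine).

templates:
  - name: alanine
    smiles: "[NH2:1][C@@H](C)[C:2](O)=O"
  - name: arginine
    smiles: "[NH2:1][C@@H](CCCNC(N)=N)[C:2](O)=O"
    variants:
      - "[NH2:1][C@@H](CCCN=C(N)N)[C:2](O)=O"
      - "[NH2:1][C@@H](CCCNC(N)=[NH2+])[C:2](O)=O"
  - name: asparagine
    smiles: "[NH2:1][C@@H](CC(N)=O)[C:2](O)=O"
  - name: aspartic acid
    smiles: "[NH2:1][C@@H](C[C:3](O)=O)[C:2](O)=O"
  - name: cysteine
    smiles: "[NH2:1][C@@H](CS)[C:2](O)=O"
  - name: glutamic acid
    smiles: "[NH2:1][C@@H](CC[C:3](O)=O)[C:2](O)=O"
  - name: glutamine
    smiles: "[NH2:1][C@@H](CCC(N)=O)[C:2](O)=O"
  - name: glycine
    smiles: "[NH2:1]C[C:2](O)=O"
  - name: histidine
    smiles: "[NH2:1][C@@H](Cc1c[nH]cn1)[C:2](O)=O"
    variants:
      - "[NH2:1][C@@H](Cc1cnc[nH]1)[C:2](O)=O"
  - name: isoleucine
    smiles: "[NH2:1][C@@H]([C@@H](C)CC)[C:2](O)=O"
  - name: leucine
    smiles: "[NH2:1][C@@H](CC(C)C)[C:2](O)=O"
  - name: lysine
    smiles: "[NH2:1][C@@H](CCCC[NH2:4])[C:2](O)=O"
  - name: methionine
    smiles: "[NH2:1][C@@H](CCSC)[C:2](O)=O"
    exclusions: [no_n_formyl]
  - name: N-formylmethionine
    smiles: "O=C[NH:1][C@@H](CCSC)[C:2](O)=O"
  - name: phenylalanine
    smiles: "[NH2:1][C@@H](Cc1ccccc1)[C:2](O)=O"
  - name: proline
    smiles: "O=[C:2](O)[C@@H]1CCC[NH:1]1"
  - name: pyrrolysine
    smiles: "[NH2:1][C@@H](CCCCNC(=O)[C@H]1[C@H](C)CC=N1)[C:2](O)=O"
  - name: selenocysteine
    smiles: "[NH2:1][C@@H](C[SeH])[C:2](O)=O"
  - name: serine
    smiles: "[NH2:1][C@@H](CO)[C:2](O)=O"
  - name: threonine
    smiles: "[NH2:1][C@@H]([C@@H](C)O)[C:2](O)=O"
  - name: tryptophan
    smiles: "[NH2:1][C@@H](Cc1c[nH]c2ccccc12)[C:2](O)=O"
  - name: tyrosine
    smiles: "[NH2:1][C@@H](Cc1ccc(O)cc1)[C:2](O)=O"
  - name: valine
    smiles: "[NH2:1][C@@H](C(C)C)[C:2](O)=O"
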