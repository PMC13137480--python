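# peptax

Structure-based peptide classification for cheminformatics and ontology
curation.  Given a molecule as SMILES (or SDF), `peptax` decides whether it
is a peptide, how many amino-acid residues it contains, how it is charged,
which skeleton subclasses and which proteinogenic amino acids it contains —
and assigns it to a 67-class peptide taxonomy modelled on the ChEBI peptide
subhierarchy, with a witness-level justification for every decision.

The intended users are ontology curators and tool builders who need a
*deterministic, purely structural* definition of "peptide" (and of
dipeptide, tripeptide zwitterion, oligopeptide cation, …) that can be
applied automatically to large molecule sets, rather than case-by-case
judgement about plausible biosynthetic routes.

## The classification scheme

A molecule is modelled as a finite structure over its heavy atoms
(hydrogens are atom attributes, aromatic rings are kekulized, formal
charges and CIP descriptors annotate atoms).  Four decisions are made:

1. **Charge.**  Every molecule falls into exactly one of five categories:
   *salt* (distinct connected components with positive and negative charge
   sums — net neutrality not required), *anion* / *cation* (net formal
   charge, when not a salt), *zwitterion* (net-neutral with opposite
   charges on non-adjacent atoms of one component; ylides excluded), else
   *neutral*.

2. **Residues and chain length.**  The molecule is mentally split at every
   heteroatom: the maximal carbon-connected components ("carbon sections"),
   extended by their neighbouring heteroatoms, form *building blocks*.  An
   amide-bond nitrogen never joins a block through the amide's carbonyl
   carbon, and a heteroatom bordering several sections may be assigned to
   only one of them.  A block containing an amino-residue nitrogen
   (N(C)(C,H…) with single or amide bonds only) and a carboxy-residue
   carbon (RC(=O)X, X a heteroatom — acid, ester, amide, …) is an
   *amino-acid residue*.  The *chain length* n is the largest number of
   pairwise-disjoint residues that n−1 amide bonds (amidic or imidic
   tautomer) connect into a single assembly.

3. **Size × charge classes.**  n ≥ 2 makes a *peptide structure*;
   oligopeptide structures have 2–9 residues, polypeptide structures ≥ 10,
   with exact classes for n = 2..5.  Size and charge combine into classes
   such as *dipeptide cation* or *tripeptide zwitterion*; the neutral
   combinations are the plain *peptide*, *dipeptide*, … classes.

4. **Skeletons and proteinogenic residues.**  Two skeleton-defined
   subclasses (*2,5-diketopiperazines* under dipeptide, *emericellamide*
   under pentapeptide) are matched as substructure templates, and residues
   of the 23 proteinogenic amino acids are detected with templates whose
   amino/carboxy groups are matched as flexible derivative points and whose
   side chains (including CIP chirality) are matched literally.

In total: 1 root + 6 size + 5 charge + 30 combination + 2 skeleton + 23
residue classes = 67 classes, 14 of which carry ChEBI cross-references.

## Worked example

```bash
$ cat demo.smi
CSCC[C@H](N)C(=O)NCCC(O)=O	met-beta-ala
NCCC(=O)N[C@@H](CCCNC(N)=[NH2+])C(O)=O	beta-alanyl-L-arginium
O=C1CNC(=O)CN1	cyclo-gly-gly

$ peptax classify --input demo.smi
id	smiles	status	chain_length	charge	classes
met-beta-ala	CSCC[C@H](N)C(=O)NCCC(=O)O	ok	2	neutral	dipeptide;dipeptide structure;methionine peptide structure;oligopeptide;oligopeptide structure;peptide;peptide structure
beta-alanyl-L-arginium	NCCC(=O)N[C@@H](CCCNC(N)=[NH2+])C(=O)O	ok	2	cation	arginine peptide structure;dipeptide cation;dipeptide structure;oligopeptide cation;oligopeptide structure;peptide cation;peptide structure
cyclo-gly-gly	O=C1CNC(=O)CN1	ok	2	neutral	2,5-diketopiperazines;dipeptide;dipeptide structure;glycine peptide structure;oligopeptide;oligopeptide structure;peptide;peptide structure
```

Reading the first row: the Met–β-Ala dipeptide has chain length 2 and is
neutral, so it receives the peptide/oligopeptide/dipeptide triple at both
the structure level and the neutral level, plus *methionine peptide
structure* because its first residue matches the L-methionine template
(β-alanine is not proteinogenic and adds no residue class).  The second row
is a cation (protonated guanidinium), so the neutral classes are replaced
by their cation counterparts — 7 classes in total.  The third row picks up
the 2,5-diketopiperazine skeleton class on top of the dipeptide classes.

`--justify` adds per-molecule witnesses (residue atom sets, amide-bond
triples, charge witness atoms) as JSON; `peptax taxonomy export` writes the
class registry as TSV or OBO stanzas; `peptax evaluate` computes per-class
agreement (Cohen's kappa) between two labelings.

The same functionality is available as a library:

```python
from peptax import parse_smiles, classify_molecule

result = classify_molecule(parse_smiles("CSCC[C@H](N)C(=O)NCCC(O)=O"))
result.chain_length   # 2
result.charge.category  # 'neutral'
sorted(result.classes)  # ['dipeptide', 'dipeptide structure', ...]
```

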