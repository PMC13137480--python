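# Methods

This note documents the model behind `peptax`, the choices made where the
design was genuinely open, and what the test suite does and does not show.

## Molecular model

A molecule is a finite structure over heavy atoms.  Hydrogens are never
graph nodes; each atom carries its attached-hydrogen count, formal charge,
element and (where assigned) CIP descriptor.  Aromatic rings are kekulized
so that every predicate can quantify over plain single/double bonds; the
pre-kekulization aromatic flag is kept on bonds because the kekulé
alternation RDKit chooses is deterministic but arbitrary, and ring-pattern
matching must not depend on it.  Input is deliberately **not**
standardised: no tautomer canonicalisation, no charge neutralisation, no
salt stripping.  The rules are written to handle non-standardised input
directly (imidic amide forms, protonated/deprotonated termini), which is
how third-party-deposited structures actually look.  Isotope labels are
ignored; explicit `[H]` atoms are folded into hydrogen counts.

## Charge categories

Salt, anion, cation, zwitterion and neutral partition all molecules.  The
salt test runs first (two distinct components with opposite charge sums;
net charge may be nonzero, as in sodium salts of polyacids), then net
charge decides anion/cation, then the zwitterion test looks for a
non-adjacent (+,−) atom pair within one component.  The non-adjacency
clause excludes ylides.  The zwitterion witness is the first qualifying
pair in atom-index order, which makes justifications deterministic.

## Residue decomposition

The decomposition splits a molecule at heteroatoms ("heteroatom-splitting
rule"): maximal carbon-connected components are the cores of *building
blocks*, each extended by its directly bonded heteroatoms.  Two rules
refine this:

* An amide nitrogen never joins the block of its carbonyl carbon — amide
  bonds are always cleanly cuttable — but it does join blocks it reaches
  through other (non-amide-carbonyl) carbon neighbours.
* A heteroatom bordering several cores is *shared* and may be assigned to
  at most one block.  Heteroatoms with no carbon neighbour at all are
  grouped with bonded such heteroatoms into carbon-free blocks (a free
  sulfate is one block, the three terminal oxygens of a C-bonded sulfonate
  are three trivial ones); these can never be residues and exist only so
  the decomposition covers all atoms.

A block is an **amino-acid residue** when it contains an amino-residue
nitrogen and a carboxy carbon.  The carboxy predicate follows the
carboxylic-acid-*derivative* definition RC(=O)X with X a single-bonded
heteroatom: esters, amides, acyl halides count; aldehydes (X=H) and
ketones (X=C) do not.  Only the carbonyl carbon is required to lie inside
the block — its oxygen/X partners may fall outside, which is what lets a
residue's C-terminal amide carbonyl anchor the residue while the amide
nitrogen belongs to the next block.  One consequence of reading the
carboxy pattern literally is that a peptide bond drawn entirely in its
imidic form (C(–OH)=N) still counts as an amide *bond*, but does not by
itself give the donor block a carboxy carbon; the donor residue then needs
some other carboxy group.  We kept the literal reading rather than
inventing an imidic carboxy variant.

## Chain length

A peptide chain of length n is n pairwise-disjoint residues connected into
one assembly by n−1 amide bonds, each joining the carbonyl carbon in one
residue to the nitrogen in another.  The search works on the candidate
graph (nodes: residue blocks; edges: amide bonds whose C and N can lie in
different blocks) and enumerates connected block subsets largest-first.
For each subset it resolves the shared heteroatoms: only shared
*nitrogens* matter (they can be amino witnesses or link nitrogens; any
other shared heteroatom is assigned arbitrarily to its lowest-indexed
block since nothing depends on it), so the assignment space is tiny in
practice and is searched exhaustively.  A subset is feasible when every
block keeps an amino nitrogen it owns and the valid links leave the subset
connected; the witness chain is read off a spanning tree, with ties broken
by ascending atom index so reruns are byte-identical.  Connectivity is
equivalent to the ordered each-residue-links-to-an-earlier-one
formulation, because such an elimination ordering exists exactly when the
residue-link graph is connected.

The search is budgeted (default 10⁶ nodes) and molecules beyond the size
limit (default 10 000 carbon components) are reported *unclassified*,
never silently truncated.  An independent exhaustive oracle
(`brute_force_chain_oracle`) re-decides the chain predicate by enumerating
every shared-heteroatom assignment, residue subset and residue ordering;
the suite checks search/oracle agreement on 200 generated molecules of up
to 40 heavy atoms (chain lengths 1–4 — small enough that the factorial
oracle stays fast, large enough to exercise shared atoms and isopeptide
links).

## Skeleton classes

2,5-diketopiperazines and emericellamides are substructure templates plus
a superclass gate (dipeptide / pentapeptide respectively), stored as SMARTS
in `data/skeletons.yaml`.  The gate carries the charge facet: an anionic
diketopiperazine ring is a dipeptide *anion* and therefore not a
2,5-diketopiperazine.  The emericellamide pattern is the macrolactone core
of N-(β-hydroxyacyl)Gly-L-Val-L-Leu-L-Ala-L-Ala with carbon wildcards at
the two hydrocarbyl positions of the hydroxyacyl unit; matching is
chirality-sensitive, the four amino-acid centres are L, the two acyl-unit
centres are fixed to the (R,R) drawing used when the template was
constructed, and unassigned stereocentres in a query fail the match (strict
reading).  The diketopiperazine ring pattern is chirality-free and leaves
side chains and N-substituents unrestricted.

## Proteinogenic residue templates

One template per proteinogenic amino acid (23: the 20 standard ones plus
selenocysteine, pyrrolysine and N-formylmethionine), stored as atom-mapped
SMILES in `data/proteinogenic.yaml` and compiled to graphs at load time.
Amino nitrogens and carboxy carbons are *flex points* matched by the
amino-/carboxy-residue predicates (so any derivative — peptide bond,
acylation, esterification, deprotonation — matches there); every other
atom must match literally in element, charge, hydrogen count, heavy-atom
degree, bonds and CIP label.  Matching uses VF2 subgraph monomorphism with
these constraints; a hit is attributed to the chain residue whose member
set contains the template's backbone carboxy carbon, and hits outside the
chain are discarded.

Decisions embedded in the templates:

* **Chirality.**  Each template records the CIP labels its L-form actually
  has (computed, not assumed): S at the α-carbon for most, R for cysteine
  and selenocysteine, (2S,3R) threonine, (2S,3S) isoleucine, (2R,3R) on
  the pyrroline ring of pyrrolysine.  D-residues and allo-forms fail the
  gate.  Glycine is achiral and unconstrained.
* **Asp/Glu vs Asn/Gln.**  The side-chain carboxy of aspartate/glutamate
  is a flex point with one exclusion: its single-bonded partner must not
  be an NH₂ nitrogen (that molecule is asparagine/glutamine).  NH with one
  hydrogen — an isopeptide bond — remains a valid aspartate/glutamate.
* **Met vs fMet.**  A methionine match whose backbone nitrogen carries a
  formyl carbon (CH=O) is suppressed; the explicit N-formylmethionine
  template reports it instead.  Acetyl and larger acyls leave methionine
  intact.
* **Tautomers.**  Histidine has both imidazole NH tautomers; arginine has
  both neutral guanidine tautomers *plus* the protonated guanidinium
  variant, so arginium-type cations are still recognised as arginine
  residues (without the variant the charged side chain would fail the
  literal-atom comparison, which contradicts how arginine-containing
  cations are actually curated).
* **Pyrrolysine ⊃ lysine.**  Pyrrolysine is an Nε-acylated lysine and
  amino groups admit acyl substituents, so every pyrrolysine residue also
  matches the lysine template.  This is a consequence of the rules, not a
  bug; the synthetic generator's expected labels account for it.

## Taxonomy

1 root (*peptide structure*) + 6 size classes + 5 charge classes + 30
size×charge combinations + 2 skeleton classes + 23 residue classes = 67.
The 14 classes shared with ChEBI carry their ChEBI identifiers; the
remaining 53 are new.  The oligopeptide/polypeptide boundary is 9/10
residues.  Naming of the new combination and residue classes follows the
pattern of the existing ones ("oligopeptide cation", "arginine peptide
structure"); residue classes attach at the peptide-structure level and are
charge-independent.  *Peptide salt* is defined as a salt in which some
component contains a chain of ≥ 2 residues; since chains never span
components, the molecule-level maximal chain already measures this.
Closure over parent links and the disjointness axioms (five charge
classes; di/tri/tetra/penta; oligo vs poly — in every charge variant) are
enforced and property-tested.

## Synthetic generator

The generator assembles peptides from monomer bodies by SMILES
concatenation (`N[C@@H](R)C(=O)` units closed by a terminal `O`), supports
eupeptide and isopeptide junctions (Asp/Glu side-chain donors, Lys
side-chain acceptor), and terminal modifications: C-terminal ester,
N-acyl, N-alkyl, C-terminal deprotonation, N-terminal protonation, and a
counter-ion (Na⁺/Cl⁻) balancing exactly one charged terminus.  Expected
labels (chain length, charge category, class set) are derived from the
construction parameters by the class algebra, independently of the
classifier, so generated peptides are ground-truth test cases.  Default
conditions for batch experiments: chain lengths uniform in 2–12, monomers
uniform over the 22 position-free proteinogenic monomers, one of six
charge-modification patterns chosen uniformly.

What the generator does *not* emulate: macrocycles, disulfide bridges and
other side-chain cross-links, depsipeptide ester backbones, phosphorylated
or glycosylated side chains, and multi-peptide assemblies.  Passing the
recovery tests therefore shows the pipeline is correct on clean linear
(iso)peptides with charged/derivatised termini; behaviour on heavily
modified natural products is exercised only by the curated fixtures.

## Numerical and procedural choices

* Kekulization and canonical SMILES come from RDKit and are deterministic
  for a given input string.
* Witness selection (zwitterion pairs, chain spanning trees, residue
  witnesses) always takes the lowest admissible atom index.
* Cohen's kappa is computed exactly from the Total/Ours/Reference/Neither
  integer counts; report output rounds half-even to 3 decimals.  A zero
  denominator raises an explicit undefined-kappa error.
* Test problem sizes: 200 molecules for search/oracle equivalence, 100 for
  the class-count floor and charge partition, 60 for full parameter
  recovery at chain lengths up to 12.

## Known limitations

* Oxidative C–C couplings between residues (vancomycin-style) are
  indistinguishable from ordinary carbon chains by the heteroatom rule;
  such molecules undercount their biosynthetic residues by design.
* Ring context is ignored: a lactone inside an aromatic ring system (e.g.
  an aminocoumarin) satisfies the carboxy-derivative pattern and counts
  toward residues, which disagrees with chemists' intuition for such
  molecules.
* A fully imidic-drawn peptide bond contributes a link but not a carboxy
  group (see above).
* The carbon-free-block grouping is a convention for atoms the residue
  rules never touch.
* Thioamides, amidines and pseudohalogen acyl derivatives are outside the
  carboxy-derivative definition and are not recognised.
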