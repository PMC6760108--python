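# Methods

## The core model

For a molecule *m* with *H(m)* heavy atoms, a **putative core** is any
substructure *c* satisfying two criteria:

1. **Relevance** — *H(c) ≥ t·H(m)*, with *t = 2/3* by default (the
   classical 2:1 core-to-substituents atom ratio). The ratio is always
   taken against the original washed molecule, never an intermediate
   fragment, and counts heavy atoms only: hydrogen counts depend on the
   capping convention and add no discriminative value.
2. **Synthetic feasibility** — *c* is the whole molecule, or is obtained
   from it by a succession of single retrosynthetic bond cleavages, each
   matching a rule of a configurable rule set, with the detached part
   discarded at every step.

Applied to a dataset, the cores induce a bipartite network *G = (U, V, E)*
of molecules and cores. Molecules sharing a core are analogs; connected
components are analog series. A series need not be pairwise analogous —
only a chain of shared-core relations is required.

## Washing

Input structures are standardized by (i) retaining the largest connected
component (salt removal), ties broken by lexicographically smallest
canonical SMILES, (ii) removing stereochemistry unless `keep_stereo` is
set, and (iii) RDKit canonicalization. Charges and tautomers are left
untouched; washing is idempotent. Identical washed structures are merged,
and WIDs are assigned in sorted canonical-SMILES order so identifiers
never depend on input order or parallel chunking. MIDs and ASIDs follow
the same sorted-assignment principle.

## Cleavage rules

The default rule set expresses the classic RECAP bond types as two-atom
SMARTS patterns whose connecting bond is cleaved: amide C–N, ester C–O,
urea N–C(=O), aliphatic amine N–C, ether C–O, acyclic olefin C=C,
quaternary N⁺–C, aromatic N–aliphatic C, lactam N–aliphatic C, biaryl
c–c, and sulfonamide S–N. Ring bonds are never cleaved. A bond matched by
several rules is cleaved once and reported with all matching rule names.
Rules are data, not code: a JSON table (`--rules`) swaps in other or
proprietary retrosynthetic schemes, and `RetroRuleSet.without()` disables
individual rules (e.g. the olefin rule, whose capping is chemically
ambiguous — see below).

Each step cuts exactly one bond; symmetric double-cut formulations of
some published rule sets are equivalent to two successive single cuts
here.

### Capping

Severed valences are terminated by one of two conventions:

* `hydrogen` (default) — the open valence is filled with hydrogens
  matching the cut bond's order. Capped graphs from different attachment
  positions may coincide, which is exactly what cross-dataset core
  identity requires; fragment heavy atoms always sum to the parent's.
  For a cleaved C=C both carbons are saturated; this is the one place
  where hydrogen capping is a chemical approximation, which is why the
  olefin rule is individually disableable.
* `wildcard` — a labelled dummy atom (`[1*]`) marks each attachment
  point, preserving positional information at the cost of core-matching
  granularity. Dummy atoms are excluded from heavy-atom counts.

### Enumeration and pruning

`enumerate_cores` runs depth-first over the cleavable bonds of the
current fragment, re-evaluating rule matches on each capped intermediate
(capping can expose new cleavable bonds: deacylating an amide leaves an
amine whose N–C bond becomes cleavable). Heavy-atom counts strictly
decrease along any cleavage sequence, so any fragment below *t·H(m)* is
pruned — it can never lead back above the threshold. Identical
intermediates are collapsed by canonical SMILES memoization. At *t = 1*
the output degenerates to the whole molecule for every input.

`enumerate_cores_bruteforce` certifies this: it materializes the entire
single-step reachability closure breadth-first with **no** pruning and
filters by the ratio afterwards, refusing molecules with more than 20
cleavable bonds. The test suite demands exact set equality between the
two on 200+ generated molecules at thresholds {0.5, 2/3, 0.8, 1.0}.

Floating-point note: the inclusive comparison `H(c) ≥ t·H(m)` is
implemented with a 1e-9 slack because counts are integers but *t* is a
float (2/3 is not representable exactly).

## Series, redundant cores, ASBS

Analog series are the connected components of *G*; singleton components
are kept and filtered only at reporting time (`--min-series-size`).
**Redundant cores** — cores incident to identical molecule sets — are
collapsed keeping the one with most heavy atoms (ties: smallest canonical
SMILES); the collection of distinct molecule sets is provably unchanged.
The core **projection** joins two cores sharing at least one molecule,
edge weights counting shared molecules.

The **ASBS** reduction restores "single molecule – single scaffold" by
iterative greedy selection: repeatedly take the core covering the most
unassigned molecules of the series (ties: more heavy atoms, then smallest
canonical SMILES) and assign its molecules to it. Every molecule is
covered (its whole-molecule core always remains available), groups are
molecule-disjoint, and greedy coverage counts are non-increasing. When a
single core covers the whole component it is the series' ASBS; otherwise
the component genuinely admits no comprehensive core and splits.

## Overlap semantics

Datasets are compared by set algebra on canonical forms at three levels:
molecules, cores, Bemis–Murcko scaffolds (acyclic molecules contribute no
scaffold). By construction unique cores ≥ unique molecules ≥ unique
scaffolds per dataset. The non-unique "cores intra" row is implemented as
the count of molecule–core incidence pairs — the only reading under which
it can exceed the unique-core row. Shared percentages are reported
relative to the union. Comparing datasets enumerated under different
configurations is refused outright, since core identity is
configuration-dependent.

## CSAR

Activities are IC50 values with units and a relation qualifier; only
exact (`=`) measurements are used, and duplicate measurements per
molecule keep the **maximum** value (conservative ChEMBL-style rule;
`keep="min"` retains the most potent instead — the convention is
genuinely ambiguous, so both are provided). Conversion happens in one
place: pIC50 = −log10(IC50 in molar).

Per core, the profile is (n, median, mean) pIC50 over incident annotated
molecules; the median is the headline statistic, the mean is reported
alongside. Cores with identical molecule sets provably carry identical
profiles, so redundant-core collapse is activity-safe. The condensed CSAR
view collapses redundant cores, restricts to profiled cores mapping to at
least 2 molecules, and exports the weighted projection with profile
attributes (GraphML). Hit-to-lead ranking orders profiles by median
(ties: n, heavy atoms, MID) — a deterministic presentation ordering, not
a statistical enrichment claim.

## Synthetic libraries

The generator plants analog series by joining a scaffold (one `[*:1]`
attachment) to substituents through rule-cleavable junction chemistry
(amide, ester, ether, amine, urea), so a single retrosynthetic step
recovers the planted core from every member. Substituent sizes are
bounded by *(1/t − 1)·H(scaffold)*, guaranteeing the relevance criterion;
junction cleavability is verified end to end by enumerating each member.
Decoys come from a pool of rule-inert ring systems and are checked post
hoc to share no core with anything else; series pairs are likewise
verified core-disjoint. Activities are drawn per molecule from
Normal(series center, spread) in pIC50 space and emitted as IC50/nM.
All randomness flows through one NumPy generator per call, so outputs are
byte-identical under a fixed seed.

A deliberately adversarial three-molecule component
(`hard_mode_component`) chains two cores such that no single core covers
all members, exercising the ASBS splitting path.

What the generator does **not** emulate: real medicinal-chemistry
libraries (no property or synthesizability realism), matched pairs
formed by coincidental substructure overlap between unrelated series,
tautomer/charge variation, or cores differing by small ring changes
(exact canonical identity is the only core-matching notion here).
Passing the recovery tests therefore shows algorithmic correctness on
clean analog structure, not robustness to the fuzziness of real data.

## Problem sizes and determinism

Default verification runs use libraries of roughly 50–220 unique
molecules (10–16 atom scaffolds, 1–6 atom substituents, ≤ 8 cleavable
bonds per molecule), sizes at which the unpruned oracle is exact and the
full suite completes in seconds. Per-molecule fragmentation is an
embarrassingly parallel map (`--jobs`, multiprocessing); because all
identifier assignment and output ordering is sort-based, outputs are
byte-identical for any worker count.

## Known limitations

* Core identity is exact canonical-string equality; near-identical cores
  (ring size changes, halogen swaps) are distinct nodes.
* Hydrogen capping of olefins saturates the alkene carbons.
* The amine rule cleaves any acyclic N(sp3)–C(sp3) bond not excluded by
  acyl/sulfonyl context; rule sets tuned to a specific project should be
  supplied via `--rules`.
* No statistical testing of core enrichment is performed; CSAR outputs
  are descriptive.
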