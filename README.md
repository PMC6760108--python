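# retrocore

Retrosynthetic molecular core analysis for compound datasets.

Classical scaffold analysis assigns each molecule a single scaffold
(Bemis–Murcko: ring systems plus linkers), which is chemically intuitive
but rigid — rings can never be substituents, acyclic molecules have no
scaffold at all, and analog relationships that a synthetic chemist would
recognize are easily missed. `retrocore` implements the generalized
alternative: for every molecule *m* it enumerates **all putative cores**,
i.e. every substructure *c* that

* retains a significant fraction of the molecule
  (*H(c) ≥ t·H(m)* heavy atoms, default *t = 2/3* — a 2:1
  core-to-substituents ratio), and
* is reachable from *m* by a succession of retrosynthetic single-bond
  cleavages under RECAP-style rules (amide, ester, urea, amine, ether,
  olefin, quaternary N, aromatic N–aliphatic C, lactam, biaryl,
  sulfonamide; ring bonds are never cut).

The whole molecule always qualifies, so every molecule has one or more
cores. Over a dataset this induces a bipartite network *G = (U, V, E)*
of molecules and cores; molecules sharing a core are analogs, and
connected components are analog series. On top of the network the package
provides:

* **Analog series & ASBS** — series detection, redundant-core collapse,
  and iterative greedy core selection restoring a single
  analog-series-based scaffold per (sub)series.
* **Dataset overlap** — set algebra between two datasets at molecule,
  core and Bemis–Murcko scaffold level (the core level is the sensitive
  one: a shared core directly materializes a cross-dataset analog
  series).
* **CSAR** — core structure–activity profiling: per-core n / median /
  mean pIC50 over the analogs mapping to each core, a condensed
  annotated core network, and "hit-to-lead" core ranking.
* **Synthetic fixtures** — seeded combinatorial libraries with planted
  cores, series structure and activity distributions, so everything is
  testable without external downloads.

It is aimed at cheminformaticians and medicinal chemists doing scaffold
content, diversity and SAR analysis on screening or natural-product
collections. Built on RDKit and NetworkX. See `docs/methods.md` for the
model details and design choices.

## Worked example

Two anilides that differ only in the acyl group:

```bash
printf 'smiles\tid\nCC(=O)Nc1ccccc1\tacetanilide\nO=CNc1ccccc1\tformanilide\n' > toy.tsv
retrocore cores toy.tsv --out-prefix toy_
```

prints

```
molecules=2 cores=3 series=1 largest=2 >=2:1 >=5:0
```

and `toy_cores.tsv` contains the molecule–core associations:

```
wid     mid     core_smiles
W0001   M0001   CC(=O)Nc1ccccc1
W0001   M0002   Nc1ccccc1
W0002   M0002   Nc1ccccc1
W0002   M0003   O=CNc1ccccc1
```

Acetanilide (10 heavy atoms) cleaves at its amide bond into aniline
(7 ≥ 2/3·10, a core) and a 3-atom fragment (discarded); formanilide
(9 heavy atoms) likewise yields aniline (7 ≥ 2/3·9). Each molecule is
also its own core. The shared aniline core makes the two molecules
analogs, so `toy_ASW.tsv` places both in series `AS0001`, and the greedy
selection picks aniline as the series' ASBS. By contrast, cleaving
N-phenylbenzamide (`O=C(Nc1ccccc1)c1ccccc1`, 15 heavy atoms) leaves
fragments of 8 and 7 atoms — both below 2/3 — so its only core is
itself.

Other subcommands: `retrocore wash`, `retrocore overlap --a A.tsv --b
B.tsv --out report.tsv`, `retrocore csar mols.tsv --activities acts.tsv
--out-prefix c_`, `retrocore fixtures --seed 3 --out fix/`. Common flags:
`--ratio` (relevance threshold), `--rules` (JSON rule table), `--jobs`
(parallel fragmentation), `--keep-stereo`.

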