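# fishcmap

Connectivity mapping (Cmap) for chemical transcriptomics: link chemical
treatment conditions by the similarity of their expression profiles, so that
a handful of differentially expressed probes can act as an exposure
biomarker and seemingly unrelated chemicals can be grouped by shared
mechanism of action (MOA).

The package is aimed at ecotoxicologists and toxicogenomics researchers
working with treated-vs-control expression matrices (microarray or
otherwise, already log2-normalized). It provides the full pipeline:

- **ROGLs** — each treated sample becomes a *rank-ordered gene list*: all N
  platform probes ranked 1..N by ascending |log2 fold-change| vs control,
  each rank signed by the direction of change.
- **Query signatures** — differential probes for a condition, called by an
  empirical-Bayes moderated t-test with Benjamini–Hochberg FDR, kept
  between 4 and 100–500 probes, each with a ±1 sign.
- **Connectivity scoring** — for signature signs *s* and ROGL signed ranks
  *r*, the score Σᵢ sᵢ·r(probeᵢ) normalized by the top-m rank sum lies in
  [−1, 1]; ROGL sets are scored by the mean over members. Significance
  comes from an empirical null of random same-size signatures (10,000 by
  default, exact enumeration on small instances), with the cutoff p ≤ 1/S
  across S interrogated sets.
- **Cross-platform translation** — probe-ID substitution through an
  orthology/equivalence table, carrying source signs and LogFCs.
- **MOA networks** — significant non-self connections aggregate into a
  weighted chemical network (max score per chemical pair), with sub-network
  filtering, neighbor counts, and an informative-connection evaluation
  against an MOA annotation table.
- **Synthetic studies** — a generator with planted MOA classes and DE
  modules, so every stage is testable without external data.

See `docs/methods.md` for the model, estimators, and design choices.

## Worked example

`examples/01_query_synthetic_study.py` simulates a compact study (4
chemicals in 2 MOA classes, 1,500 probes, 4+4 fish per condition), builds
the E2 signature, and queries the per-chemical ROGL sets:

```
reference database: 16 ROGLs in S=4 sets, critical p = 1/4 = 0.250

query signature E2_1x_M_liver_48hr: m=40 probes, RTI=0.0267, mean |LogFC|=2.00

rank  set      score        p  significant  self
   1  E2       0.993   0.0000  yes          yes
   2  EE2      0.608   0.0000  yes          no
   3  FIP      0.045   0.2440  yes          no
   4  MUS      0.006   0.4720  no           no
```

Reading the output: the signature's own condition scores ≈ 1 (its probes
occupy the top ranks of its own ROGLs with matching signs) and is the best
hit; the ER-agonist classmate EE2 scores strongly because the two chemicals
perturb overlapping probe modules; the unrelated GABA-class chemicals sit
near 0. RTI (relative transcriptome impact) is the fraction of the
platform called differentially expressed — here 2.7 %. The other examples
show cross-platform translation (`02_cross_platform_translation.py`) and
all-vs-all MOA network construction (`03_moa_network.py`).

A thin CLI mirrors the library for shell pipelines:

```sh
fishcmap simulate --seed 7 --out study/
fishcmap rogl-build --matrix study/matrix.tsv --samples study/samples.tsv \
    --out db/ --set-by chemical
fishcmap signature --matrix study/matrix.tsv --samples study/samples.tsv --out sigs/
fishcmap query --signature sigs/E2_1x_M_liver_48hr.sig.tsv --rogl-db db/ \
    --nsim 10000 --seed 17 --out results.tsv
```

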