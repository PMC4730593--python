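"""Query a synthetic multi-chemical study: signature -> ROGL sets -> ranking.

Simulates a compact study (4 chemicals in 2 MOA classes, 1,500 probes,
4 treated + 4 control fish per condition), derives the E2 query signature by
moderated-t/FDR, and interrogates the per-chemical ROGL sets.  The printed
table shows, per set, the mean normalized connectivity score (1.0 = the
signature's probes occupy the top ranks with matching signs), the empirical
p-value against 1,000 random signatures, and whether the connection clears
the 1/S significance cutoff.  Expect the signature's own chemical first with
a score near 1, its ER-agonist classmate next, and the unrelated class near
score 0.  (With only S=4 sets the 1/S cutoff is permissive; real reference
databases with dozens of sets make it strict.)
"""

import fishcmap as fc

cfg = fc.SimConfig(
    n_probes=1500,
    module_size=40,
    effect_size=2.0,
    chemicals=(
        ("E2", "ER agonist"), ("EE2", "ER agonist"),
        ("FIP", "GABA antagonist"), ("MUS", "GABA antagonist"),
    ),
    platform_id="SIM1K5",
)
matrix, samples, truth = fc.simulate_study(cfg, seed=101)

rogls = fc.build_rogls(matrix, samples)
sets = fc.group_rogls(rogls, keys=("chemical",))
print(f"reference database: {len(rogls)} ROGLs in S={len(sets)} sets, "
      f"critical p = 1/{len(sets)} = {fc.critical_pvalue(len(sets)):.3f}\n")

treated = fc.treated_ids_for_condition(samples, chemical="E2")
stats = fc.differential_stats(matrix, samples, treated)
metrics = fc.impact_metrics(stats)
sig = fc.select_signature(stats, platform_id=cfg.platform_id)
print(f"query signature {sig.name}: m={sig.m} probes, "
      f"RTI={metrics.rti:.4f}, mean |LogFC|={metrics.mean_abs_logfc:.2f}\n")

results = fc.query(sig, sets, n_sim=1000, seed=17)
print(f"{'rank':>4}  {'set':<6} {'score':>7} {'p':>8}  significant  self")
for r in results:
    print(f"{r.rank:>4}  {r.set_id:<6} {r.score:>7.3f} {r.p_value:>8.4f}  "
          f"{'yes' if r.significant else 'no':<11}  {'yes' if r.self else 'no'}")
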