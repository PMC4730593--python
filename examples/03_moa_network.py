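"""Aggregate all-vs-all queries into a chemical MOA network.

Runs every condition's signature against every chemical's ROGL set on a
synthetic study with three planted MOA classes, keeps the highest-scored
significant non-self connection per chemical pair, and prints the resulting
network: its edges (weight = normalized connectivity score), each node's
neighbor count, and the informative-connection rate (queries whose top-5
significant hits include a same-class chemical).  Chemicals sharing a class
should be each other's strongest neighbors.
"""

import fishcmap as fc

cfg = fc.SimConfig(n_probes=4000, module_size=60, effect_size=1.5)
matrix, samples, truth = fc.simulate_study(cfg, seed=404)
sets = fc.group_rogls(fc.build_rogls(matrix, samples), keys=("chemical",))

cache, results_by = {}, {}
for chem, _cls in cfg.chemicals:
    stats = fc.differential_stats(
        matrix, samples, fc.treated_ids_for_condition(samples, chemical=chem)
    )
    try:
        sig = fc.select_signature(stats, platform_id=cfg.platform_id)
    except fc.NoSignatureError:
        print(f"{chem}: too few DEGs for a signature (condition kept as ROGLs only)")
        continue
    results_by[sig.name] = fc.query(sig, sets, n_sim=1000, seed=55, null_cache=cache)

summary, _ = fc.evaluate_informative(results_by, fc.moa_table(cfg), k=5)
print(f"\ninformative connections: {summary.formatted()}\n")

net = fc.build_network([r for res in results_by.values() for r in res])
cls = dict(cfg.chemicals)
print(f"network: {net.n_nodes} chemicals, {net.n_edges} edges")
for a, b, d in sorted(net.graph.edges(data=True), key=lambda e: -e[2]["weight"]):
    tag = "same class" if cls[a] == cls[b] else "cross class"
    print(f"  {a:>5} -- {b:<5} weight {d['weight']:.3f}  ({tag})")
print("\nneighbor counts:", fc.node_degrees(net))

sub = fc.filter_subnetwork(net, min_score=0.3)
print(f"\nstrong sub-network (score >= 0.3): {sub.n_nodes} nodes, {sub.n_edges} edges")
fc.export_network(net, "scratch_moa_network.sif", fmt="sif")
print("full network exported to scratch_moa_network.sif (Cytoscape-ready)")
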