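"""Domain enrichment heat-map data, the significance bipartite network and
GO over-representation per paralog network.

Run: python examples/04_domains_and_go.py
"""

import tempfile
from pathlib import Path

from paralognet import GeneratorConfig, generate_bundle
from paralognet.domains import build_bipartite, domain_enrichment_tests, domain_frequencies, top_n_union
from paralognet.go import OntologyDAG, enrich
from paralognet.netbuild import assemble_full_network, extract_paralog_subnetwork

bundle = generate_bundle(GeneratorConfig(seed=1))
net = assemble_full_network(bundle.interactions, bundle.annotations, bundle.isoform_map)
pnets = {
    lab: extract_paralog_subnetwork(net, lab, bundle.isoform_map)
    for lab in sorted(bundle.isoform_map)
}

profiles = [domain_frequencies(p) for p in pnets.values()]
union = top_n_union(profiles, 10)
print(f"top-10 union spans {len(union)} domains; RRM pairwise Fisher p (gamma row):")
print(domain_enrichment_tests(profiles, "RRM").loc["gamma"].map("{:.2e}".format).to_dict())
print("gamma's exclusive partners carry RRM at 8x weight -> gamma is the enriched row\n")

bip = build_bipartite(profiles, domains=union, alpha=0.01)
print(f"bipartite significance network at p<=0.01: {len(bip.edges)} isoform-domain edges")
print("per-domain isoform degree:", dict(sorted(bip.domain_degree.items())), "\n")

with tempfile.TemporaryDirectory() as td:
    obo = Path(td) / "go.obo"
    obo.write_text(bundle.obo_text)
    dag = OntologyDAG.from_obo(obo)
universe = set(net.proteins)
annotations = {pid: set(rec.go_terms) for pid, rec in net.proteins.items()}
results = enrich(
    set(pnets["gamma"].partner_ids) & universe, universe, annotations, dag,
    namespace="biological_process",
)
print("top 3 enriched terms in the gamma network:")
for r in results[:3]:
    print(f"  {r.term_id} ({r.name}): k={r.k}/{r.n}, K={r.K}/{r.N}, p={r.p:.2e}, q={r.q:.2e}")
print("the boosted term tops the list; its ancestors inherit the signal via true-path propagation")
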