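"""Region-stratified PTM composition, acetylation burden and phospho/acetyl
crosstalk across the seven networks.

Run: python examples/03_ptm_composition.py
"""

from paralognet import GeneratorConfig, generate_bundle
from paralognet.netbuild import assemble_full_network, extract_paralog_subnetwork
from paralognet.ptm import acetylation_burden, composition_table, crosstalk_association

bundle = generate_bundle(GeneratorConfig(seed=1))
net = assemble_full_network(bundle.interactions, bundle.annotations, bundle.isoform_map)
pnets = {
    lab: extract_paralog_subnetwork(net, lab, bundle.isoform_map)
    for lab in sorted(bundle.isoform_map)
}

print("percent of domain phosphosites that are pTyr, per network:")
for lab, pnet in pnets.items():
    ct = composition_table(pnet)
    print(f"  {lab:8s} {ct.percentages.loc['pY', 'domain']:5.1f}%")
print("epsilon stands out: its exclusive partners carry a 2.5x domain-pTyr rate\n")

burden = acetylation_burden(list(pnets.values()))
print(burden["counts"])
row = burden["site_p_matrix"].loc["zeta"].drop("zeta")
print(f"\nzeta vs others, per-partner acetyl-site Wilcoxon: min p = {row.min():.2e}")
print("zeta's partners carry roughly twice the acetyl-lysine burden of the rest\n")

table, p, _ = crosstalk_association(pnets["zeta"], "Y")
print(f"zeta pTyr x acK protein-level association: {table}, Fisher p = {p:.3g}")
print("(acetylation is coupled to nuclear/NLS partners in the generator)")
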