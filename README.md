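# paralognet

Comparative analysis of the interaction networks of paralogous hub
proteins.  The motivating system is the human 14-3-3 family: seven strictly
conserved paralogs (β, γ, ε, η, σ, θ, ζ) that bind hundreds of
phospho-serine/threonine clients.  Whether the paralogs are interchangeable
or specialized is a systems-level question: it lives in *which* partners
each isoform binds, how those partners are wired, which domains they carry,
where their modifications sit, and which processes they enrich.

`paralognet` implements that comparison as a tested pipeline:

* **Network assembly** — hub + kinase + substrate interaction network from
  TSV tables, with per-protein annotations (domains, intrinsic-disorder
  segments, PTM sites, GO terms, localization, kinase groups); paralog
  subnetwork extraction and partner-set similarity
  J(A, B) = |A∩B| / |A∪B|.
* **Edge orientation** — a categorical naive Bayes classifier trained on
  edges of known direction (kinase → substrate) turns the undirected network
  into a directed one.
* **Triad motifs** — census of the 13 connected 3-node digraph classes
  (7 = feed-forward loop, 3 = cascade, ...), with per-class z-scores and
  empirical p-values p = (1 + #{random ≥ real}) / (R + 1) against a
  switching null that conserves in/out-degrees and reciprocity exactly.
* **PTM composition and crosstalk** — pSer/pThr/pTyr/acetyl-Lys counts
  stratified by region (domain / disordered / other), pairwise Fisher exact
  comparisons across isoform networks, acetylation burden, protein-level
  phospho×acetyl association, kinase-group profiles, localization and NLS
  statistics.
* **Domain analysis** — per-network domain frequencies, top-N heat-map
  data, pairwise enrichment, the p ≤ 0.01 domain–isoform significance
  network, phospho-/acetyl-modified domain profiles and domain-clade
  ("club") profiles.
* **GO enrichment** — OBO parsing, true-path propagation, upper-tail
  hypergeometric tests with BH q-values, adaptive thresholding and
  cross-isoform −log₁₀ p comparison tables.
* **Synthetic data** — a ground-truth generator that emits every input file
  with the statistical structure above (tunable partner overlap, region-
  dependent PTM rates, isoform-specific planted effects, planted
  feed-forward loops), so calibration and power of every statistic are
  testable without any external download.

See `docs/methods.md` for models, defaults and design decisions.

## Worked example

```python
from paralognet import (
    GeneratorConfig, generate_bundle, assemble_full_network,
    extract_paralog_subnetwork, jaccard_matrix, composition_table,
)

bundle = generate_bundle(GeneratorConfig(seed=1))
net = assemble_full_network(bundle.interactions, bundle.annotations,
                            bundle.isoform_map)
print(net.summary())
# {'n_nodes': 739, 'n_edges': 1307, 'n_isoforms': 7, 'n_clients': 679}

pnets = {lab: extract_paralog_subnetwork(net, lab, bundle.isoform_map)
         for lab in sorted(bundle.isoform_map)}
print(round(jaccard_matrix(list(pnets.values())).loc["theta", "beta"], 3))
# 0.27   <- the generator's theta-beta overlap target

ct = composition_table(pnets["epsilon"])
print(ct.percentages.round(1)["domain"].to_dict())
# {'pS': 31.0, 'pT': 15.2, 'pY': 53.8}
```

The last line shows the planted ε-specific effect: inside domains, tyrosine
becomes the dominant phospho-acceptor of ε partners (~54% of domain
phosphosites versus ~33% in the other networks), overtaking serine — the
composition inversion that singles this isoform out.

Or run everything from a shell:

```bash
paralognet run --seed 1 --out-dir out/
# writes net.graphml, directed.graphml, jaccard.csv, motifs.csv,
# composition.csv, burden*.csv, domain_*.csv, enrichment.csv, ... +
# manifest.json with config + input/output hashes
```

`examples/` contains one short script per capability.

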