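"""From a KGML pathway definition to a colored-map URL.

Parses a minimal KGML document, filters currency metabolites, builds the
reaction network, embeds it, and (with simulated expression for its
genes) produces a KEGG-style map-coloring URL for the up/down calls.
"""

import numpy as np
import pandas as pd

import pathwave as pw

KGML = """\
<pathway name="path:hsa00999" title="toy pathway">
 <entry id="1" name="hsa:10" type="gene" reaction="rn:R1"/>
 <entry id="2" name="hsa:20 hsa:21" type="gene" reaction="rn:R2"/>
 <entry id="3" name="hsa:30" type="gene" reaction="rn:R3"/>
 <reaction id="11" name="rn:R1"><substrate name="cpd:A"/><product name="cpd:B"/></reaction>
 <reaction id="12" name="rn:R2"><substrate name="cpd:B"/><product name="cpd:C"/></reaction>
 <reaction id="13" name="rn:R3"><substrate name="cpd:C"/><product name="cpd:H2O"/></reaction>
</pathway>
"""

doc = pw.parse_kgml(KGML)
degrees = pw.metabolite_degrees([doc])
degrees["cpd:H2O"] = 50  # pretend whole-model degree: ubiquitous water
doc = pw.filter_metabolites(doc, pw.MetaboliteFilterPolicy(), degrees)
net = pw.build_reaction_network(doc)
print(f"{net.pathway_id}: {net.n_nodes} reactions, {net.n_edges} edges "
      "(water removed, so no spurious edges through it)")

pathway = pw.preprocess_networks([net])[0]

# simulated two-class expression; class A is the alphabetically first label
# ("normal"), so an "up" call means higher in normal than in tumor
rng = np.random.default_rng(1)
samples = [f"T{i}" for i in range(6)] + [f"N{i}" for i in range(6)]
labels = {s: ("tumor" if s[0] == "T" else "normal") for s in samples}
genes = sorted({g for gs in net.node_genes.values() for g in gs})
values = pd.DataFrame(rng.normal(size=(len(genes), 12)), index=genes, columns=samples)
values.loc["hsa:10", [s for s in samples if s[0] == "N"]] += 3.0
expr = pw.ExpressionMatrix(values=values, class_labels=labels)

res = pw.run_analysis([pathway], expr, n_perm=200, seed=0)
r = res.results[0]
print(f"score {r.score:.2f}, p_adj {r.p_adjusted:.3g}, calls: {r.direction_calls}")
for url in pw.kegg_color_urls(res.results):
    print(url)
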