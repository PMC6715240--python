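# gmlayout

Grid- and modularity-based layout (GML) of biological networks, with
layout-quality metrics — a Python library and `gml` command-line tool.

Biological interaction networks (protein–protein interactions, pathways,
regulatory circuits) are modular: groups of molecules are densely wired
internally and sparsely connected to the rest. Force-directed drawings of
such networks collapse into hairballs, and plain grid layouts scatter
modules. GML draws the network in three stages so that the module structure
is visible at a glance while nodes stay on distinct grid points:

1. **Preprocessing** — nodes in user-*predefined* modules (complexes,
   pathways known a priori) are set aside; the remaining nodes are
   partitioned into *pseudo* modules by multilevel (Louvain) modularity
   maximization.
2. **Module layout** — each module becomes a single point on the grid and
   the positions are optimized under the cost
   `C_module = Σ w_hk·d_hk`, where `d_hk` is the Manhattan distance and the
   weight `w_hk` grows with the number of edges `e_hk` between modules `h`
   and `k`. Every module is then expanded into a square region of side
   `l_h = ⌈2·√n_h⌉` anchored at `(x_h·l′, y_h·l′)` with
   `l′ = max_h l_h + margin`, so regions never overlap.
3. **Grid optimization** — all nodes are placed inside their module regions
   minimizing `C_node = Σ w_ij·d_ij`. Same-module pairs weigh **40 / 0 /
   −10** at shortest-path lengths 1 / 2 / ≥3; adjacent pairs in *different*
   modules get an extra **+40**, pulling bridge endpoints to the facing
   sides of their regions and reducing edge crossings.

Both optimization stages use *reoptimization-after-perturbation*: greedy
single-entity descent to a local minimum, then random kicks (each entity
moves to a random vacant neighboring point with probability 0.2 by default)
followed by re-descent, keeping the cheaper layout each round.

Layout quality is scored by four measures: the **connectivity F-measure**
(per-node harmonic mean, weight α = 0.5, of circle precision and recall,
maximized over the circle radius), the **relative edge length** (total
Manhattan edge length / (layout area × m)), and the **edge-edge** and
**node-edge crossing ratios** (crossings normalized by edge pairs and
node–edge pairs).

## Worked example

Generate a planted-partition network with four 25-node modules
(`p_in = 0.3`, `p_out = 0.01`), lay it out, and score the result:

```sh
$ gml synth --sizes 25,25,25,25 --p-in 0.3 --p-out 0.01 --seed 1 -o net.tsv --truth truth.tsv
wrote net.tsv: 100 nodes, 363 edges

$ gml layout net.tsv -o out --seed 1 --niter-module 60 --niter-grid 40
wrote out/layout.tsv (100 nodes, 4 modules, cost 45800)

$ gml metrics net.tsv out/layout.tsv
connectivity_f  relative_edge_length  edge_edge_ratio  node_edge_ratio  alpha  eps
0.574980        0.008008              0.026726         0.013128         0.5    0.5
```

The clustering recovered the four planted modules
(`out/report.json` → `"n_modules": 4`); `out/regions.tsv` lists each
module's square region (here four 10×10 squares, since
`l_h = ⌈2√25⌉ = 10`), and `out/layout.tsv` gives every node's integer
coordinates, module and predefined flag. For comparison, a seeded random
placement of the same 100 nodes scores `connectivity_f = 0.193` and
`edge_edge_ratio = 0.237`: the GML layout triples the F-measure and cuts
edge crossings roughly ninefold, because neighbors end up spatially close
and inter-module edges run between — not through — the module regions.

Predefined modules are supplied as a two-column TSV (`node-id<TAB>module-id`)
via `--predefined`; those nodes bypass clustering and keep their module
verbatim. All flags can live in a YAML config (`--config`), and
`--svg` adds a rendering.

## Library use

```python
from gmlayout import GMLParams, layout_network, evaluate_layout, example_network_24

net, predefined = example_network_24()
res = layout_network(net, predefined, GMLParams(seed=1))
print(evaluate_layout(res.layout, net))
```

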