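# popnet — multilayer population-scale opportunity networks

`popnet` constructs and analyzes a population-scale *social opportunity
network*: a multilayer graph over all residents of a country in one
analysis year, with a layer per formal tie type — close family (C),
extended family (E), household (H), school (S), neighbors (N), work (W)
— inferred from administrative-register-style person-year tables. Such
networks model who *could* interact through kinship, co-residence,
shared school cohorts, shared properties and shared workplaces; they are
the substrate for studies of segregation, epidemics, and social
opportunity. Real register microdata are legally restricted, so the
package includes a synthetic register generator reproducing the
structural features the construction needs (single-person households,
move-out dynamics, immigrants without family links, multi-modal property
sizes, heavy-tailed firm sizes); the construction and measures are
identical for real panels with the same schema.

The model: an undirected single-aspect multilayer network with
supra-adjacency A[u,v,l] ∈ {0,1}, no coupling edges. Per-layer degree
k_{u,l} = Σ_v A[u,v,l], total degree k_u = Σ_l k_{u,l}, and unique
neighbors k′_u (the flattened degree). Edge embeddedness counts common
neighbors with layer multiplicity, emb(u,v) = Σ_{l1,l2} Σ_w
A[u,w,l1]·A[v,w,l2]; zero-embeddedness edges get a *tie range* (shortest
alternative path after removing the edge), and those with tie range ≥ 6
are *wormholes* — long-range bridges. Closure distinguishes pure
triangles (all three edges inside one layer) from multilayer ones:
excess closure c_excess(u) = (T_unique − T_pure) / (P_u − T_pure), with
P_u = C(k_u,2) − Σ_v C(m_uv,2) the alter tie pairs. Components,
exact giant-component diameter, sampled mean shortest path and sampled
closeness (|V|−1 / Σ_v d(u,v)) complete the characterization. See
`docs/methods.md` for definitions, algorithms and limitations.

## Worked example

```python
import popnet

cfg = popnet.GeneratorConfig(population_size=20_000, rng_seed=2017)
registry = popnet.generate_population(cfg)          # person-year panel
layers = popnet.build_all_layers(registry, 2017, seed=2017)
snap = registry[registry.year == 2017]
net = popnet.MultilayerNetwork(snap.person_id.to_numpy(), layers,
                               layers=popnet.LAYERS)
table = popnet.layer_accumulation_table(net, seed=2017, n_sources=300)
print(table.to_string(index=False))
```

prints (20,000 synthetic persons):

```
     layers  vertices  edges  components  gc_share  diameter  mean_path  mean_path_se
          C     16564  23588        8111   0.00095         8   2.964912      0.164882
      C+E+H     16564  24161        8111   0.00095         8   2.964912      0.164882
    C+E+H+N     19981 190762          74   0.98665        14   5.919221      0.031335
  C+E+H+N+S     20000 345594           1   1.00000         7   3.689556      0.009958
C+E+H+N+S+W     20000 437091           1   1.00000         6   3.125210      0.008566
```

Reading the rows: family layers alone leave the population in thousands
of small components (family ties can only be inferred where co-residence
falls inside the 2000–2017 panel window, and extended-family ties need
two such generations — the `layer_summary` for this run has only 573 E
edges against 23,588 C edges). Adding the first affiliation layer
(neighbors) assembles 98.7% of the population into one giant component;
school and work then shrink distances to small-world scale (diameter 6,
mean shortest path ≈ 3.1). The closure census on the same run reports
9.7% of flattened edges with embeddedness zero and a mean excess closure
of 0.007 — closure here overwhelmingly forms inside single affiliation
cliques.

The same pipeline is scripted in `analysis/01_generate_registry.py` …
`analysis/06_life_course_profiles.py` (run them in order from the
repository root; tables land in `results/`, bulk data in `scratch/`),
and as a CLI: `popnet run --out out/ --population 10000 --seed 1`.

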