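"""Co-expression modules: Pearson correlation of HVGs + k-means, submodules.

On a generated scene, each cell-type marker program forms a co-expressed
gene block; k-means on the rows of the gene-gene correlation matrix should
recover those blocks as modules, and average-linkage clustering inside one
module exposes its submodule structure.
"""

from scarst import coexpression as cx, preprocess, synthetic

lattice = synthetic.build_lattice(30, 30)
scene = synthetic.make_scene(lattice, time_dpi=14, seed=1)
counts = synthetic.sample_counts(scene, synthetic.default_programs(), (), 300, seed=1)
norm = preprocess.log_normalize(counts)

hvgs = preprocess.select_hvg(norm, 100)
corr = cx.gene_correlation(norm, hvgs)
modules = cx.kmeans_modules(corr, k=8, seed=0)

print("modules (id = size rank), first members:")
for m in modules:
    head = ", ".join(m.genes[:6]) + (" ..." if len(m) > 6 else "")
    print(f"  module {m.module_id:2d} ({len(m):3d} genes): {head}")

fib_module = next(m for m in modules if "Col1a1" in m.genes)
maps = cx.module_spatiotemporal_map(fib_module, {14: norm}).set_index("barcode")
in_core = scene.truth_labels == "fibroblast"
print(f"\nfibroblast module (id {fib_module.module_id}) mean expression: "
      f"{maps.mean_expression[in_core.to_numpy()].mean():.3f} in the fibrotic core vs "
      f"{maps.mean_expression[(~in_core).to_numpy()].mean():.3f} elsewhere")

_, subs = cx.submodule_hierarchy(fib_module, corr, cut_height=0.5)
print(f"\nsubmodules of module {fib_module.module_id} at cut height 0.5 on 1 - r "
      f"(collagens co-fluctuate most tightly):")
for name, genes in subs.items():
    print(f"  {name}: {', '.join(genes[:8])}{' ...' if len(genes) > 8 else ''}")
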