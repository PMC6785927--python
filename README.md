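# pareto-metab

Multi-objective flux balance analysis of cancer metabolism: sample
Pareto-optimal flux states of a genome-scale metabolic model under four
competing objectives, fit cell-line-specific models from omics data,
score gene ablations by their deviation from the Pareto surface, and
identify metabolic enzymes whose activation or inhibition selectively
impairs proliferative or Warburg-shifted cells.

## Who this is for

Computational/systems biologists working with constraint-based models
(COBRA-style stoichiometric models with gene-protein-reaction rules) who
want to move beyond single-objective FBA: instead of assuming cells
maximise growth alone, the package treats the cell state as a trade-off
between four objectives and analyses the geometry of the resulting
Pareto surface.

## The model

For a stoichiometric matrix *S* and flux vector *v* with bounds
*lb ≤ v ≤ ub*, all analyses run over the steady-state polytope
*S·v = 0*. Four objectives are evaluated on each flux configuration:

1. **biomass synthesis** — flux of the biomass reaction (maximise);
2. **ATP production** — flux of the ATP hydrolysis/maintenance reaction
   (maximise);
3. **enzyme cost** — Σᵢ wᵢ·|vᵢ| over gene-associated reactions, a proxy
   for the limited solvent capacity of the cytoplasm (minimise);
4. **carbon uptake** — Σⱼ cⱼ·max(0, −vⱼ) over exchange reactions, with
   cⱼ the carbon count of the exchanged metabolite (minimise).

A flux configuration is **Pareto-optimal** when no feasible
configuration improves all four objectives simultaneously. The front is
sampled by the **ε-constraint method**: maximise one objective (biomass
by default) while the other three are constrained at grid levels
spanned by the four single-objective extremes, with lexicographic
clean-up of alternate optima and a final dominance filter.

Downstream analyses:

* **Cell-line models** — each line is represented by the Pareto
  solutions most similar to its proteomics (Spearman rank agreement
  between enzyme abundance and gene-level flux engagement) and its
  consumption/release (CORE) exchange fluxes (Lin's concordance, which
  is magnitude-aware).
* **PDS (Pareto deviation score)** — after knocking a gene down through
  its GPR rule and re-predicting flux by MOMA (minimisation of
  metabolic adjustment, a Euclidean projection QP), the fitness impact
  is the Euclidean distance of the perturbed objective point to the
  sampled front in min–max-normalised objective space. PDS = 0 exactly
  on the surface; genes with PDS 0 in every line are called
  nonessential.
* **Target identification** — the front is projected onto planes of
  (phenotype, enzyme flux), where the phenotype is growth rate or an
  in-silico Warburg magnitude (lactate secretion / O₂ uptake, the
  ECAR/OCR analogue). Per-phenotype-bin flux extremes form upper/lower
  envelopes; the **monotonousness score** (Spearman correlation of an
  envelope with the phenotype) plus a boundary-proximity requirement on
  the cell-line models yields four target classes
  (growth/Warburg × promoting/suppressing) and their overlaps.

## Worked example

Everything below runs on a built-in fixture, `ferm-resp-net`: glucose is
either fermented to lactate (cheap in catalytic capacity, 2 ATP/glucose)
or respired with O₂ (capacity-hungry, 30 ATP/glucose) under a shared
capacity budget, with biomass drawing on glucose, ATP and capacity.

```python
from pareto_metab import GridSpec, epsilon_constraint_sample, make_fixture
from pareto_metab.cellline import fit_cell_line
from pareto_metab.synthetic import make_synthetic_panel
from pareto_metab.pds import gene_essentiality_screen, essentiality_summary
from pareto_metab.targets import classify_targets, calls_table

net = make_fixture("ferm-resp-net")
front = epsilon_constraint_sample(net, grid=GridSpec(levels=10))
print(f"sampled {len(front)} Pareto solutions")

panel = make_synthetic_panel(net, front, 20, noise_sigma=0.05, seed=1)
models = [fit_cell_line(net, front, p, top_fraction=0.05) for p in panel.profiles]

screen = gene_essentiality_screen(net, front, models[:10])
print(essentiality_summary(screen).to_string(index=False))

calls = calls_table(classify_targets(net, front, models, n_bins=12))
print(calls[calls.phenotype == "warburg"].to_string(index=False))
```

Output:

```
sampled 724 Pareto solutions
  gene  n_nonzero_lines  essential
 g_bio               10       True
g_ferm               10       True
g_resp               10       True
g_tglc                0      False
g_tlac               10       True
 g_to2               10       True
enzyme   direction  monotonousness  boundary_proximity
 g_bio suppressing            -1.0                0.65
g_ferm   promoting             1.0                1.00
g_resp suppressing            -1.0                1.00
g_tglc suppressing            -1.0                0.55
g_tlac   promoting             1.0                1.00
 g_to2 suppressing            -1.0                1.00
```

Reading this: ablating the biomass, fermentation or respiration enzymes
pushes every fitted line off the Pareto surface (PDS > 0, "essential"),
while the glucose transporter knockout collapses the cell to the idle
zero-flux state — which is itself Pareto-optimal (zero cost, zero
carbon), so PDS calls it nonessential. On the Warburg axis, the
fermentation enzyme and the lactate exporter are *promoting* (their
lower flux bound rises with the ECAR/OCR proxy: inhibiting them
selectively hits Warburg-shifted states), while the respiration chain is
*suppressing* (its upper bound falls as the Warburg ratio rises:
activating it is incompatible with strongly fermentative states).

The same workflow runs from the shell:

```bash
pareto-metab synth fixture --name ferm-resp-net --out model.tsv
pareto-metab sample model.tsv --grid 10 --out front/
pareto-metab synth panel model.tsv front/ --n 20 --sigma 0.05 --seed 1 --out omics/
pareto-metab fit model.tsv front/ --proteomics omics/proteomics.tsv \
    --core omics/core.tsv --top-fraction 0.05 --out models.tsv
pareto-metab pds model.tsv front/ models.tsv --out pds.tsv
pareto-metab targets model.tsv front/ models.tsv --out calls.tsv
```

SBML models load the same way (`pareto-metab model validate model.xml`);
the biomass and ATP-maintenance reactions are auto-detected by name
pattern or can be passed explicitly.

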