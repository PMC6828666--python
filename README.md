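# openpocket

Structure-based discovery of protein–protein interaction inhibitors often
fails at the first step: the target pocket, typically a shallow interface
site or kinase *exosite*, is collapsed in apo crystal structures — flexible
side chains fall into the cavity and leave nothing for a docking engine to
dock into.  `openpocket` is a library and CLI for preparing such sites for
virtual screening and for triaging the resulting hit lists.  It is aimed at
computational chemists and structural bioinformaticians working on
conformationally plastic binding sites (the motivating system is the
CK2α/CK2β kinase subunit interface, a small ~832 Å² interface with a
shallow, flexible pocket on the catalytic subunit).

## What it computes

**Pocket detection.** The Lennard–Jones potential of the protein is mapped
on a regular grid,

    P0(r) = Σ_a [ A_a / d¹²(a,r) − B_a / d⁶(a,r) ],

truncated at −0.8 kcal/mol to keep only attractive regions, and smoothed by
an (unnormalized) Gaussian convolution

    P(r) = (1/λ³) ∫ exp(−d²(x,r)/λ²) P0(x) dx,      λ = 2.6 Å.

Connected regions below a contour level become *pocket envelopes*; their
volume and sphericity give a druggability verdict (drug-like volume range
150–800 ų by default).

**Fumigation.**  To open a collapsed pocket, its side chains (except
Ala/Gly/Cys) are shaved to alanine, an atom density map

    D(r) = Σ_a exp(−d²(a,r)/w_a²)

is built on a 0.5 Å grid (w_a = van der Waals radius) and convolved with
λ = 12 Å to give a coarse map D_c that fills the cavities.  The difference
F(r) = D_c(r) − D(r) is large exactly where a ligand could sit.  F is then
used as a repulsive pseudo-ligand: the original side chains are sampled by
Metropolis Monte Carlo over their χ torsions with w_F·Σ F(atom) added to a
minimal physical energy (soft clash repulsion + 3-fold torsion term), the
twenty best conformers are kept, and each is re-scored by the pocket
detector.  Collapsed pockets open; rigid geometry never moves (backbone is
fixed).

**Hit triage.**  Post-docking hit lists flow through a funnel: binding
score ≤ −30 (score units, more negative is better), greedy leader
clustering on fingerprint Tanimoto similarity to remove chemical
redundancy, drug-like property windows (MW, logP, logS), a ≤ 8 Å
minimum-distance filter to an anchor residue at the pocket bottom, and
top-100 selection.  Every decision is logged per compound.  A weighted
full-atom binding score combiner

    S_bind = E_int + TΔS_tor + E_vw + α₁E_el + α₂E_hb + α₃E_hp + α₄E_sf

is provided for re-scoring merged complexes (the α weights must be supplied
for quantitative use).

## Worked example

Everything is testable without downloads: the `fixtures` command generates
synthetic structures, including a collapsed-pocket toy — a quasi-spherical
scaffold whose lysine side chains are posed into the cavity.

```sh
openpocket fixtures collapsed_pocket --seed 0 --out fx
openpocket fumigate fx/collapsed_pocket.pdb --center 0,0,0 \
    --radius 12 --steps 10000 --seed 1 --out fum
```

prints (abridged):

```
rank  step  E_combined  E_physical  penalty  max_volume_A3  druggable
1     9240  38.287      51.913      -13.626  368.0          1
2     9239  38.323      52.037      -13.714  368.0          1
3     9250  38.367      51.578      -13.211  368.0          1
...
apo max envelope volume: 0.0 A^3; best fumigated: 370.0 A^3
```

The collapsed input has no envelope at all (`apo max volume 0.0`): the
side chains obstruct the cavity.  After sampling against the F map, the
best conformers carry a ~370 ų, roughly spherical envelope — a druggable
pocket — and their map penalty (−13.6) is far below the input pose's
(+70.2), i.e. the side chains have vacated the repulsive pseudo-ligand
density.  Ranked conformer PDBs, the F map (CCP4) and a JSON metadata
record land in `fum/`.

Other entry points: `openpocket pockets` (envelope report for any PDB),
`openpocket triage` (the funnel on a TSV hit table),
`openpocket interface-area` (per-side buried SASA between two chain sets).
The same functionality is available as a library (`openpocket.fumigate`,
`openpocket.find_pockets`, `openpocket.run_funnel`, ...).

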