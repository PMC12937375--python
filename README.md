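# contactatlas

Residue-interaction **persistence atlases** from multi-replica molecular
dynamics trajectories of glycoprotein complexes.

Microsecond-scale MD of antibody Fc fragments bound to Fcγ receptors (and
of glycoproteins generally) produces a question the raw trajectory does not
answer directly: *which residue pairs actually hold the interface together,
for how long, and how does engineering (mutations, glycan remodelling)
rewire that network?* `contactatlas` answers it by

1. detecting **hydrogen bonds, ionic interactions and van der Waals
   contacts** geometrically, frame by frame;
2. converting per-frame hits into per-pair **cumulative durations and
   occupancies** over an analysis window, aggregated across independent
   replicas (mean ± sample SD, longest continuous segment);
3. classifying every contact by **layer** — protein–protein,
   protein–glycan, glycan–glycan, intra- vs interchain (a glycan inherits
   the carrier chain of the asparagine it is attached to);
4. comparing variants with **two-sided Welch t-tests** on per-replica
   durations, plus unique-contact lists;
5. reporting duration heatmaps, persistent-contact tables, glycan anomeric
   C1 RMSF profiles, and RMSD/R_g convergence checks.

A first-class **synthetic trajectory generator** drives designated residue
pairs between contact and no-contact geometry with exact two-state Markov
kinetics (Gillespie-sampled, stationary-initialised) plus Gaussian jitter,
so every stage of the pipeline is validated against analytic ground truth:
stationary occupancy k_on/(k_on+k_off), exponential dwell times 1/k_off,
and an exactly known contact universe.

## The statistics in brief

For a residue pair *p* and interaction type, each replica *r* yields a
boolean presence series over the analysis window \[t₀, t₁); the summaries

- occupancy  θ̂ₚᵣ = (frames present)/(window frames),
- cumulative duration  Dₚᵣ = θ̂ₚᵣ · (t₁ − t₀),

are aggregated with a fixed replica denominator (a replica without the
contact contributes 0 ns), giving mean ± SD over replicas. Stated filters:
a per-replica occupancy cutoff (keep if max_r θ̂ₚᵣ ≥ 0.10) and inclusive
mean-duration floors (display ≥ 45 ns, persistent ≥ 200 ns). Variants are
compared per pair with Welch's t on {Dₚᵣ}, Welch–Satterthwaite degrees of
freedom, no multiplicity correction (the number of tests is reported).

## Worked example

```python
from contactatlas import ContactPersistenceModel
from contactatlas.synthetic import two_variant_specs

spec_a, spec_b = two_variant_specs(seed=0, n_frames=2000)   # 200 ns demo
res_a = ContactPersistenceModel.from_spec(spec_a, window=(20.0, 200.0)).fit()
res_b = ContactPersistenceModel.from_spec(spec_b, window=(20.0, 200.0)).fit()

res_a = res_a.filter("occupancy_min", 0.10)
res_b = res_b.filter("occupancy_min", 0.10)
print(res_a.summary(top=6))
```

```text
========================================================================
                       Contact Persistence Atlas
========================================================================
Complex:            variant-A
Replicas:           4
Window:             [20, 200) ns (180 ns)
Frames analysed:    [1800, 1800, 1800, 1800] (dt = 0.1 ns)
Contact records:    10
Filters:            occupancy_min>=0.1
Detection:          {'hbond_max_da_dist_A': 3.5, 'hbond_min_dha_angle_deg': 120.0, 'ionic_max_group_dist_A': 4.0, 'vdw_radius_slack_A': 0.5, 'implicit_hydrogens': True}
------------------------------------------------------------------------
pair                          type   layer                     mean±SD ns
------------------------------------------------------------------------
A:LEU240–C:TRP117             vdw    protein-protein/interchain  159.7±38.7
A:ASP241–C:LYS120             ionic  protein-protein/interchain  142.2±43.4
A:ASP241–C:LYS120             vdw    protein-protein/interchain  142.2±43.4
A:ASP241–C:LYS120             hbond  protein-protein/interchain  130.3±39.2
B:ASP265–b:NAG1               hbond  protein-glycan/intrachain   117.3±55.1
B:ASP265–b:NAG1               vdw    protein-glycan/intrachain   117.3±55.1
========================================================================
```

Each row is one residue pair: the interchain salt bridge A:Asp241–C:Lys120
was programmed with k_on = 0.05/ns, k_off = 0.005/ns (stationary occupancy
0.909 → expected ≈ 164 ns of the 180 ns window), and the glycan contact
B:Asp265–b:GlcNAc1 with symmetric rates (expected 90 ns); the fitted means
recover both within the replica scatter. Comparing against variant B, in
which that salt bridge was destabilised twenty-fold:

```python
diff = res_a.compare_frame(res_b)
print(diff[["res_a", "res_b", "type", "delta_ns", "p", "status", "significant"]]
      .head(5).to_string(index=False))
```

```text
 res_a  res_b  type  delta_ns        p status  significant
   241    120 ionic    84.350 0.023523 shared         True
   241    120   vdw    84.350 0.023523 shared         True
   241    120 hbond    77.125 0.022109 shared         True
   239    121 hbond   -49.825 0.243823 shared        False
   239    121   vdw   -49.825 0.243823 shared        False
```

Exactly the programmed difference is flagged (the same physical contact
also registers under the shadowing vdW/H-bond criteria); the untouched
pairs stay within statistical variability.

## Command line

```bash
contact-atlas simulate -o fixtures/ --seed 1        # write 2-variant fixture + config
contact-atlas run -c fixtures/config.yaml           # full pipeline -> report bundle
contact-atlas compare A/atlas.tsv B/atlas.tsv -o diff.tsv
```

The report bundle contains per-complex atlas TSVs (with JSON provenance
sidecars), persistent-contact tables, duration heatmaps, glycan C1 RMSF
profiles, convergence summaries, differential tables, and a provenance
JSON recording every threshold and seed. Reruns with the same config and
seed are byte-identical.

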