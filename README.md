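# korbias

Conformational-state classification and signaling-bias quantification for the
κ-opioid receptor (KOR) and other class A GPCRs.

Biased agonists activate one transducer pathway (G protein or β-arrestin)
preferentially over the other at the same receptor. This package implements
the two computational halves of that analysis:

- **State analysis of MD trajectories.** Each frame is superposed onto a
  reference structure (TM2/TM3/TM5 Cα), reduced to five geometric
  observables — the T94^2.39^–D334^8.47^ contact distance, the signed TM7
  rotation at S324^7.47^, the Q115^2.60^ rotamer dihedral, the
  K227^5.39^–E297^6.58^ salt-bridge distance, and the W287^6.48^ vertical
  displacement — and classified into one of three intracellular states:
  *occluded* if the contact distance is < 3.5 Å, else *alternative* if the
  TM7 rotation is < −20°, else *canonical*. Occupancies are computed per
  replicate and compared between ligand conditions with exact rank or
  permutation tests.
- **Operational-model bias analysis.** Dose–response curves are fit globally
  per pathway with the Black–Leff model, B = 10^(X·n)·10^(logτ·n),
  Y = Emax·B/[B + (10^X + 10^K_A)^n] (Emax = 100, Hill slope n shared across
  ligands). Transduction coefficients log(τ/K_A) give
  Δlog(τ/K_A) = log(τ/K_A)_ligand − log(τ/K_A)_reference per pathway,
  ΔΔlog(τ/K_A) between pathways, and the bias factor 10^ΔΔlog with a
  t-based 95% CI. Radioligand competition (one-site Ki via Cheng–Prusoff)
  and dissociation kinetics (one-phase decay, t½ = ln2/koff) are included.

Seeded synthetic-data generators with machine-readable ground truth make
every stage testable without any external data; see `docs/methods.md` for
the model details and design decisions.

## Worked example

```python
import numpy as np
import korbias as kb

# --- trajectory side: simulate, classify, summarize -----------------------
T = np.array([[0.90, 0.05, 0.05], [0.05, 0.90, 0.05], [0.05, 0.05, 0.90]])
pres = kb.StatePrescription(n_frames=2000, seed=42, transition_matrix=T)
traj, labels, truth = kb.simulate_trajectory(pres)

rmap = kb.default_residue_map()
spec = kb.AlignmentSpec.from_tm_ranges(rmap, kb.reference_frame())
metrics = kb.compute_frame_metrics(traj, rmap, spec)
occ = kb.occupancy({"rep0": kb.classify_frames(metrics)})
print({k: round(v, 3) for k, v in occ.pooled.items()})

# --- pharmacology side: full bias pipeline on synthetic assays ------------
data, _ = kb.simulate_dose_response(kb.example_assay_prescription(seed=7))
results = kb.compute_bias(data, "U50,488", "G", "arrestin")
for lig, r in results.items():
    ci = f"({r.ci_low:.1f}-{r.ci_high:.1f})" if r.ci_low else ""
    print(f"{lig:12s} bias factor {r.bias_factor:6.2f} {ci}")
```

prints

```
{'occluded': 0.294, 'alternative': 0.352, 'canonical': 0.353}
U50,488      bias factor   1.00
WMS-X600     bias factor   0.11 (0.1-0.2)
nalfurafine  bias factor   7.41 (5.1-10.8)
```

The occupancy line is the frame-weighted fraction of simulation time the
synthetic receptor spends in each state (close to the planted Markov chain's
uniform-ish stationary distribution). The bias factors are relative to the
reference U50,488 (exactly 1 by construction) with ΔΔlog taken G-minus-
arrestin: values above 1 mean G-protein bias, below 1 arrestin bias. The
generating truth for this dataset was a factor of 6 toward G for the
nalfurafine-like ligand and 10 toward arrestin (factor 0.1) for the
WMS-X600-like ligand; the fitted estimates recover these within the
noise-driven CIs.

A `korbias` console script exposes the same workflows from the shell
(`korbias simulate`, `classify`, `occupancy`, `compare`, `bias`, `fit-dr`,
`fit-ki`, `fit-dissoc`).

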