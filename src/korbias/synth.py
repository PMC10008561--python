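"""Seeded synthetic-data generators with machine-readable ground truth.

Every pipeline stage is testable without external downloads: trajectories are
emitted as reduced-topology multi-model structures whose atoms are placed
analytically so that each geometric observable equals a prescribed per-state
target plus Gaussian noise, and assay datasets are drawn from the closed-form
operational, competition and dissociation models.  All generators are pure
functions of (prescription, seed).

The synthetic receptor contains exactly the atoms the metrics need — T94 OG1,
D334 OD1/OD2, S324/L325 Cα, Q115 C/CA/CG/CD, K227 NZ, E297 OE1/OE2, the W287
ring, and a fixed Cα anchor set standing in for the TM2/TM3/TM5 alignment
helices.  Because the anchors never move, analysis-time superposition is the
identity and the planted metric values are recovered exactly at zero noise.
No attempt is made to emulate real MD kinetics or a full receptor topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pharm import operational_response
from .states import STATE_ORDER, MetricConfig, StateLabel
from .traj import AtomRecord, Frame, ResidueMap, Trajectory, default_residue_map

_CHAIN = "A"

# Fixed alignment anchors (synthetic TM2/TM3/TM5 Cα), non-collinear by design.
_ANCHORS = {
    96: (-20.0, -15.0, 0.0), 97: (-20.0, -15.0, 3.0), 98: (-18.0, -13.0, 6.0),
    135: (25.0, -15.0, 0.0), 136: (25.0, -15.0, 3.0), 137: (23.0, -17.0, 6.0),
    230: (0.0, -25.0, 0.0), 231: (0.0, -25.0, 3.0), 232: (2.0, -23.0, 6.0),
}

# Planar indole-ring template for W287, centered at the origin.
_TRP_RING = {
    "CG": (-1.2, 0.7, 0.0), "CD1": (-2.5, 0.5, 0.0), "CD2": (-0.8, -0.6, 0.0),
    "NE1": (-2.9, -0.8, 0.0), "CE2": (-1.9, -1.5, 0.0), "CE3": (0.5, -1.1, 0.0),
    "CZ2": (-1.9, -2.9, 0.0), "CZ3": (0.5, -2.5, 0.0), "CH2": (-0.7, -3.2, 0.0),
}
_W287_CENTER = np.array([0.0, 20.0, 0.0])
_Q115_ORIGIN = np.array([-15.0, 0.0, 0.0])
_S324_CA = np.array([10.0, 10.0, 0.0])
_K227_NZ = np.array([20.0, 0.0, 0.0])

#: Reference (crystal-like) metric values realized in the generator's frame 0
#: surrogate: canonical distance, no rotation, gauche Q115, formed salt bridge.
REFERENCE_METRICS = {
    "t94_d334_distance": 6.5,
    "tm7_rotation": 0.0,
    "q115_dihedral": -65.0,
    "k227_e297_distance": 3.0,
    "w287_z_displacement": 0.0,
}


@dataclass
class MetricTargets:
    """Per-state target values of the five observables."""

    t94_d334_distance: float
    tm7_rotation: float
    q115_dihedral: float = -65.0
    k227_e297_distance: float = 3.0
    w287_z_displacement: float = 0.0


#: Study-condition state targets: the occluded state forms the TM2–TM7 contact
#: (and TM7 is rotated clockwise), the alternative state is rotated without the
#: contact, the canonical state is neither.
DEFAULT_STATE_TARGETS: dict[StateLabel, MetricTargets] = {
    StateLabel.OCCLUDED: MetricTargets(3.0, -30.0, -65.0, 3.0, -1.0),
    StateLabel.ALTERNATIVE: MetricTargets(6.5, -35.0, 60.0, 3.0, -1.0),
    StateLabel.CANONICAL: MetricTargets(6.5, 0.0, -65.0, 3.0, 0.0),
}

DEFAULT_NOISE_SD = {
    "t94_d334_distance": 0.3,
    "tm7_rotation": 5.0,
    "q115_dihedral": 10.0,
    "k227_e297_distance": 0.3,
    "w287_z_displacement": 0.2,
}


@dataclass
class StatePrescription:
    """What the synthetic trajectory should realize.

    Either ``labels`` (a fixed state sequence) or ``transition_matrix`` (a 3×3
    row-stochastic matrix over occluded/alternative/canonical, sampled as a
    Markov chain started from its stationary distribution) must be given.
    """

    n_frames: int = 1000
    seed: int = 0
    targets: Mapping[StateLabel, MetricTargets] = field(
        default_factory=lambda: dict(DEFAULT_STATE_TARGETS)
    )
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    labels: Sequence[StateLabel] | None = None
    transition_matrix: np.ndarray | None = None
    ar1_phi: float = 0.0  # AR(1) metric autocorrelation for stress tests

    def validate(self, cfg: MetricConfig | None = None) -> None:
        cfg = cfg or MetricConfig()
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be non-negative")
        t = self.targets
        if t[StateLabel.OCCLUDED].t94_d334_distance >= cfg.occluded_distance_cutoff:
            raise ValueError("occluded target distance must be below the contact cutoff")
        alt = t[StateLabel.ALTERNATIVE]
        if alt.t94_d334_distance < cfg.occluded_distance_cutoff:
            raise ValueError("alternative target distance must be above the contact cutoff")
        if alt.tm7_rotation >= cfg.tm7_rotation_cutoff:
            raise ValueError("alternative target rotation must be below the rotation cutoff")
        can = t[StateLabel.CANONICAL]
        if (can.t94_d334_distance < cfg.occluded_distance_cutoff
                or can.tm7_rotation < cfg.tm7_rotation_cutoff):
            raise ValueError("canonical targets must sit above both cutoffs")
        if self.labels is None and self.transition_matrix is None:
            raise ValueError("provide either a label sequence or a transition matrix")
        if self.transition_matrix is not None:
            T = np.asarray(self.transition_matrix, dtype=float)
            if T.shape != (3, 3) or not np.allclose(T.sum(axis=1), 1.0):
                raise ValueError("transition matrix must be 3×3 row-stochastic")


def _stationary_distribution(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    return pi / pi.sum()


def _sample_labels(pres: StatePrescription, rng: np.random.Generator) -> list[StateLabel]:
    if pres.labels is not None:
        labels = [StateLabel(l) for l in pres.labels]
        if len(labels) != pres.n_frames:
            raise ValueError("label sequence length must equal n_frames")
        return labels
    T = np.asarray(pres.transition_matrix, dtype=float)
    pi = _stationary_distribution(T)
    state = rng.choice(3, p=pi)
    out = []
    for _ in range(pres.n_frames):
        out.append(STATE_ORDER[state])
        state = rng.choice(3, p=T[state])
    return out


def _place_atoms(metrics: Mapping[str, float]) -> list[AtomRecord]:
    """Analytic atom placement realizing the given metric values exactly."""
    d = metrics["t94_d334_distance"]
    rot = np.radians(metrics["tm7_rotation"])
    phi = np.radians(metrics["q115_dihedral"])
    ds = metrics["k227_e297_distance"]
    wz = metrics["w287_z_displacement"]
    atoms = [
        AtomRecord("CA", "GLY", _CHAIN, resnum, np.array(pos))
        for resnum, pos in _ANCHORS.items()
    ]
    atoms += [
        AtomRecord("OG1", "THR", _CHAIN, 94, np.zeros(3)),
        AtomRecord("OD1", "ASP", _CHAIN, 334, np.array([d, 0.0, 0.0])),
        AtomRecord("OD2", "ASP", _CHAIN, 334, np.array([d + 1.0, 0.5, 0.0])),
        AtomRecord("CA", "SER", _CHAIN, 324, _S324_CA),
        AtomRecord(
            "CA", "LEU", _CHAIN, 325,
            _S324_CA + np.array([1.5 * np.cos(rot), 1.5 * np.sin(rot), 1.5]),
        ),
        AtomRecord("C", "GLN", _CHAIN, 115, _Q115_ORIGIN + np.array([0.0, 1.0, 0.0])),
        AtomRecord("CA", "GLN", _CHAIN, 115, _Q115_ORIGIN),
        AtomRecord("CG", "GLN", _CHAIN, 115, _Q115_ORIGIN + np.array([1.5, 0.0, 0.0])),
        AtomRecord(
            "CD", "GLN", _CHAIN, 115,
            _Q115_ORIGIN + np.array([1.5, np.cos(phi), np.sin(phi)]),
        ),
        AtomRecord("NZ", "LYS", _CHAIN, 227, _K227_NZ),
        AtomRecord("OE1", "GLU", _CHAIN, 297, _K227_NZ + np.array([ds, 0.0, 0.0])),
        AtomRecord("OE2", "GLU", _CHAIN, 297, _K227_NZ + np.array([ds + 1.0, 0.5, 0.0])),
    ]
    atoms += [
        AtomRecord(name, "TRP", _CHAIN, 287, _W287_CENTER + np.array(pos) + np.array([0.0, 0.0, wz]))
        for name, pos in _TRP_RING.items()
    ]
    return atoms


def reference_frame() -> Frame:
    """The crystal-structure surrogate all synthetic frames are measured against."""
    return Frame(0, _place_atoms(REFERENCE_METRICS))


def simulate_trajectory(
    pres: StatePrescription,
    rmap: ResidueMap | None = None,
    replicate_id: str = "rep0",
    condition: str = "",
) -> tuple[Trajectory, list[StateLabel], pd.DataFrame]:
    """Emit a synthetic trajectory plus planted labels and realized metrics.

    Each frame's observables equal the state's targets plus Gaussian noise
    (optionally AR(1)-correlated across frames); the returned truth table holds
    the realized (noisy) metric values, so classifier tests never re-derive
    them.  Fully reproducible from the prescription's seed.
    """
    pres.validate()
    if rmap is None:
        rmap = default_residue_map(_CHAIN)
    rng = np.random.default_rng(pres.seed)
    labels = _sample_labels(pres, rng)
    metric_names = list(DEFAULT_NOISE_SD)
    n = pres.n_frames
    noise = {m: np.zeros(n) for m in metric_names}
    for m in metric_names:
        sd = pres.noise_sd.get(m, 0.0)
        eps = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        if pres.ar1_phi != 0.0 and sd > 0:
            phi = pres.ar1_phi
            ar = np.empty(n)
            ar[0] = eps[0]
            for i in range(1, n):
                ar[i] = phi * ar[i - 1] + np.sqrt(1.0 - phi**2) * eps[i]
            eps = ar
        noise[m] = eps
    frames, rows = [], []
    for i, label in enumerate(labels):
        tgt = pres.targets[label]
        metrics = {m: getattr(tgt, m) + noise[m][i] for m in metric_names}
        # keep distances physical
        metrics["t94_d334_distance"] = max(metrics["t94_d334_distance"], 0.1)
        metrics["k227_e297_distance"] = max(metrics["k227_e297_distance"], 0.1)
        frames.append(Frame(i, _place_atoms(metrics)))
        rows.append({"frame_index": i, **metrics, "label": label.value})
    traj = Trajectory(frames, replicate_id=replicate_id, condition=condition)
    return traj, labels, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dose–response generation from the operational model
# ---------------------------------------------------------------------------

@dataclass
class AssayPrescription:
    """Operational-model truth for a multi-ligand, multi-pathway assay.

    ``ligands`` maps ligand → pathway → (logτ, logK_A).  Defaults mirror a
    typical normalized assay: 8 concentrations spanning −12…−5 log10 M,
    3 independent experiments, Gaussian noise with SD 2% of the system
    maximum, shared Hill slope 1.
    """

    ligands: Mapping[str, Mapping[str, tuple[float, float]]]
    hill: float = 1.0
    emax: float = 100.0
    log_conc: Sequence[float] = field(default_factory=lambda: np.linspace(-12.0, -5.0, 8))
    replicates: int = 3
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.log_conc) < 4:
            raise ValueError("need at least 4 concentrations")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def simulate_dose_response(pres: AssayPrescription) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a tidy dose–response dataset; returns (data, truth) tables.

    Truth rows carry logτ, logK_A, n and the transduction coefficient
    log(τ/K_A) per (ligand, pathway).
    """
    pres.validate()
    rng = np.random.default_rng(pres.seed)
    X = np.asarray(list(pres.log_conc), dtype=float)
    data_rows, truth_rows = [], []
    for ligand, pathways in pres.ligands.items():
        for pathway, (logtau, logka) in pathways.items():
            truth_rows.append({
                "ligand": ligand, "pathway": pathway, "logtau": logtau,
                "logKA": logka, "n": pres.hill, "log_tau_ka": logtau - logka,
            })
            clean = operational_response(X, logtau, logka, pres.hill, pres.emax)
            for rep in range(1, pres.replicates + 1):
                noisy = clean + (
                    rng.normal(0.0, pres.noise_sd, size=X.size)
                    if pres.noise_sd > 0 else 0.0
                )
                for xi, yi in zip(X, noisy):
                    data_rows.append({
                        "ligand": ligand, "pathway": pathway, "replicate": rep,
                        "log_conc_M": xi, "response": yi,
                    })
    return pd.DataFrame(data_rows), pd.DataFrame(truth_rows)


def example_assay_prescription(seed: int = 0, **kwargs) -> AssayPrescription:
    """Three-ligand study mirror: a balanced reference, a G-protein-biased
    agonist (true bias factor 6 vs the reference) and an arrestin-biased
    agonist (true bias factor 10 toward arrestin)."""
    lg6 = np.log10(6.0)
    # Reference log(τ/K_A): 8.0 (G), 7.6 (arrestin).  The G-biased ligand has
    # Δlog = 1.6 in G, so its arrestin log(τ/K_A) is set to 7.6 + 1.6 − log10(6)
    # for a true ΔΔ(G − arr) of +log10(6).
    ligands = {
        "U50,488": {"G": (0.5, -7.5), "arrestin": (0.4, -7.2)},
        "nalfurafine": {"G": (0.6, -9.0), "arrestin": (0.3, 0.3 - (9.2 - lg6))},
        # ΔΔ(G − arr) = −log10(10) = −1
        "WMS-X600": {"G": (0.4, -7.8), "arrestin": (0.5, -8.3)},
    }
    return AssayPrescription(ligands=ligands, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Binding-assay generation
# ---------------------------------------------------------------------------

@dataclass
class CompetitionPrescription:
    log_ki: float = -9.0
    radioligand_conc: float = 1e-9
    radioligand_kd: float = 1e-9
    top: float = 2000.0
    bottom: float = 500.0
    log_conc: Sequence[float] = field(default_factory=lambda: np.linspace(-12.0, -5.0, 8))
    replicates: int = 3
    noise_sd: float = 0.0  # CPM
    seed: int = 0


def simulate_competition(pres: CompetitionPrescription) -> tuple[pd.DataFrame, dict]:
    """One-site competition data with the IC50 placed by inverse Cheng–Prusoff."""
    if pres.radioligand_conc <= 0 or pres.radioligand_kd <= 0:
        raise ValueError("radioligand concentration and Kd must be positive")
    if pres.noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(pres.seed)
    log_ic50 = pres.log_ki + np.log10(1.0 + pres.radioligand_conc / pres.radioligand_kd)
    X = np.asarray(list(pres.log_conc), dtype=float)
    clean = pres.bottom + (pres.top - pres.bottom) / (1.0 + 10.0 ** (X - log_ic50))
    rows = []
    for rep in range(1, pres.replicates + 1):
        noisy = clean + (rng.normal(0.0, pres.noise_sd, X.size) if pres.noise_sd > 0 else 0.0)
        rows += [
            {"log_conc_M": xi, "cpm": yi, "replicate": rep} for xi, yi in zip(X, noisy)
        ]
    truth = {"log_ki": pres.log_ki, "log_ic50": float(log_ic50),
             "top": pres.top, "bottom": pres.bottom}
    return pd.DataFrame(rows), truth


@dataclass
class DissociationPrescription:
    y0: float = 3000.0
    ns: float = 300.0
    koff: float = 0.0231  # min^-1 → t½ ≈ 30 min
    times_min: Sequence[float] = field(
        default_factory=lambda: [2.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0]
    )
    replicates: int = 3
    noise_sd: float = 0.0  # CPM
    seed: int = 0


def simulate_dissociation(pres: DissociationPrescription) -> tuple[pd.DataFrame, dict]:
    """One-phase exponential dissociation time course (2 min – 2 h window)."""
    if pres.koff <= 0:
        raise ValueError("koff must be positive")
    if pres.noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(pres.seed)
    t = np.asarray(list(pres.times_min), dtype=float)
    clean = (pres.y0 - pres.ns) * np.exp(-pres.koff * t) + pres.ns
    rows = []
    for rep in range(1, pres.replicates + 1):
        noisy = clean + (rng.normal(0.0, pres.noise_sd, t.size) if pres.noise_sd > 0 else 0.0)
        rows += [{"time_min": ti, "cpm": yi, "replicate": rep} for ti, yi in zip(t, noisy)]
    truth = {"y0": pres.y0, "ns": pres.ns, "koff": pres.koff,
             "t_half": float(np.log(2.0) / pres.koff)}
    return pd.DataFrame(rows), truth
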