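"""Synthetic connectome cohorts with tumor-like perturbations.

Emulates the ingredients of a brain-tumor modeling study so the entire
pipeline is exercisable without patient data: weighted modular connectomes
with heavy-tailed (lognormal) weights, region sizes coupled to connection
strength, focal "tumor" perturbations that rescale incident edges and inflate
region sizes, nuisance covariates, and ground-truth "empirical" FC produced by
the forward model itself at a known coupling G_true — which makes parameter
recovery a testable claim.

Group labels follow the study design: CON (controls), MEN (meningioma-like),
GLI (glioma-like), with default counts 11 / 14 / 11.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import (
    DisconnectedGraphError,
    FunctionalConnectome,
    StructuralConnectome,
    is_connected,
    make_region_table,
)
from .fitting import derive_seed, simulate_fc
from .neural import RwwParameters, SimulationConfig, tune_fic

__all__ = [
    "CohortSpec",
    "TumorPerturbation",
    "Subject",
    "generate_sc",
    "apply_tumor",
    "generate_ground_truth_fc",
    "generate_cohort",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """Could not produce a connected network under the requested spec."""


@dataclass(frozen=True)
class CohortSpec:
    """Study-design knobs for a synthetic cohort.

    ``density`` is the fraction of nonzero off-diagonal pairs; weights follow
    a lognormal law (heavy-tailed, like filtered streamline counts) modulated
    by region size so strength and size correlate, as in real parcellations.
    """

    n_regions: int = 68
    n_modules: int = 4
    density: float = 0.30
    weight_mu: float = -2.0
    weight_sigma: float = 1.0
    size_mu: float = float(np.log(1500.0))
    size_sigma: float = 0.4
    n_control: int = 11
    n_meningioma: int = 14
    n_glioma: int = 11
    module_ratio: float = 4.0   # within- vs between-module edge probability
    g_true_range: tuple = (0.6, 1.6)
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 2 or self.n_modules < 1:
            raise ValueError("need n_regions >= 2 and n_modules >= 1")
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if min(self.n_control, self.n_meningioma, self.n_glioma) < 0:
            raise ValueError("group counts must be >= 0")


@dataclass(frozen=True)
class TumorPerturbation:
    """Focal lesion model: rescale incident edges, inflate region sizes."""

    node_set: tuple
    weight_factor: float = 0.5
    size_inflation: float = 1.5

    def __post_init__(self):
        if self.weight_factor < 0:
            raise ValueError("weight_factor must be >= 0")
        if self.size_inflation < 1:
            raise ValueError("size_inflation must be >= 1")


@dataclass
class Subject:
    """One synthetic participant: connectome, metadata, and provenance."""

    subject_id: str
    group: str                      # CON | MEN | GLI
    sc: StructuralConnectome
    region_table: pd.DataFrame
    covariates: dict
    g_true: float
    perturbation: TumorPerturbation | None = None
    fc_emp: FunctionalConnectome | None = None
    fit: object = None              # FitResult, filled in by the user
    j_true: np.ndarray | None = None


def _module_labels(n_regions: int, n_modules: int) -> np.ndarray:
    return np.arange(n_regions) % n_modules


def _edge_probabilities(spec: CohortSpec) -> tuple[float, float]:
    labels = _module_labels(spec.n_regions, spec.n_modules)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(spec.n_regions, k=1)
    f_in = same[iu].mean()
    f_out = 1.0 - f_in
    if spec.n_modules == 1 or spec.density == 1.0:
        return spec.density, spec.density
    p_out = spec.density / (spec.module_ratio * f_in + f_out)
    p_in = spec.module_ratio * p_out
    if p_in > 1.0:  # saturate within-module, make up the density between
        p_in = 1.0
        p_out = min(1.0, (spec.density - f_in) / f_out) if f_out else 1.0
        p_out = max(p_out, 0.0)
    return p_in, p_out


def generate_sc(spec: CohortSpec, rng: np.random.Generator | None = None,
                max_attempts: int = 100
                ) -> tuple[StructuralConnectome, pd.DataFrame]:
    """Sample a connected modular weighted connectome plus its region table.

    Edges follow a planted-block model (within-module probability above
    between-module), weights a lognormal law scaled by sqrt(size_i * size_j)
    so strength tracks region size; the matrix is rescaled so the maximum
    weight is 1.  Reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_regions
    labels = _module_labels(n, spec.n_modules)
    p_in, p_out = _edge_probabilities(spec)
    same = labels[:, None] == labels[None, :]
    sizes = np.maximum(rng.lognormal(spec.size_mu, spec.size_sigma, size=n), 10.0)
    size_scale = np.sqrt(np.outer(sizes, sizes)) / np.exp(spec.size_mu)
    for _ in range(max_attempts):
        p = np.where(same, p_in, p_out)
        iu = np.triu_indices(n, k=1)
        present = rng.random(len(iu[0])) < p[iu]
        raw = rng.lognormal(spec.weight_mu, spec.weight_sigma, size=len(iu[0]))
        w = np.zeros((n, n))
        w[iu] = present * raw
        w = w + w.T
        w *= size_scale
        if w.max() > 0:
            w = w / w.max()
        np.fill_diagonal(w, 0.0)
        coords = rng.uniform(0.0, 140.0, size=(n, 3))  # mm-scale embedding
        dist = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        lengths = np.where(w > 0, dist, 0.0)
        sc = StructuralConnectome(w, lengths, [f"region_{i}" for i in range(n)])
        if is_connected(sc):
            table = make_region_table(sc.region_ids, np.round(sizes).astype(int))
            table["module"] = labels
            return sc, table
    raise GenerationError(
        f"no connected graph at density {spec.density} after {max_attempts} attempts"
    )


def apply_tumor(sc: StructuralConnectome, region_table: pd.DataFrame,
                pert: TumorPerturbation
                ) -> tuple[StructuralConnectome, pd.DataFrame]:
    """Apply a focal perturbation: incident edge weights of the tumor node set
    are multiplied by ``weight_factor`` (once per edge), region sizes by
    ``size_inflation``, and tumor flags are set.  Raises if the perturbed
    network disconnects.
    """
    nodes = np.asarray(sorted(pert.node_set), dtype=int)
    if len(nodes) == 0:
        raise ValueError("node_set must be nonempty")
    if nodes.min() < 0 or nodes.max() >= sc.n_regions:
        raise ValueError("node_set outside region range")
    incident = np.zeros((sc.n_regions, sc.n_regions), dtype=bool)
    incident[nodes, :] = True
    incident[:, nodes] = True
    w = np.where(incident, sc.weights * pert.weight_factor, sc.weights)
    lengths = None if sc.lengths is None else np.where(w > 0, sc.lengths, 0.0)
    out = StructuralConnectome(w, lengths, sc.region_ids)
    if not is_connected(out):
        raise DisconnectedGraphError("tumor perturbation disconnects the network")
    table = region_table.copy()
    table.loc[table.index[nodes], "size"] = np.round(
        table["size"].to_numpy()[nodes] * pert.size_inflation
    ).astype(int)
    table.loc[table.index[nodes], "is_tumor"] = True
    return out, table


def generate_ground_truth_fc(sc: StructuralConnectome, g_true: float,
                             sim_config: SimulationConfig | None = None,
                             params: RwwParameters | None = None,
                             tr: float = 2.1,
                             fic_kwargs: dict | None = None
                             ) -> tuple[FunctionalConnectome, dict]:
    """Run the full forward model at a known coupling to fabricate an
    "empirical" FC with ground-truth provenance (g_true, tuned J, seed)."""
    sim_config = sim_config or SimulationConfig()
    params = (params or RwwParameters()).with_(G=float(g_true))
    fic = tune_fic(sc, params, sim_config, **(fic_kwargs or {}))
    fc = simulate_fc(sc, params.with_(J=fic.j), sim_config, tr)
    provenance = {
        "g_true": float(g_true),
        "seed": int(sim_config.seed),
        "tr": float(tr),
        "j_true": fic.j,
        "rates": fic.rates,
    }
    return fc, provenance


def _covariates(rng: np.random.Generator, group: str, tr: float) -> dict:
    is_patient = group != "CON"
    return {
        "age": float(np.clip(rng.normal(55.0, 12.0), 18.0, 85.0)),
        "sex": int(rng.random() < 0.5),
        "motivation": float(1.0 / rng.normal(650.0, 80.0)),  # 1 / MOT latency
        "distress": float(np.clip(rng.normal(40.0, 10.0), 20.0, 80.0)),
        "lesion_volume": float(rng.lognormal(np.log(12_000.0), 1.0)) if is_patient else 0.0,
        "handedness": float(1.0 if rng.random() < 0.85 else rng.uniform(-1.0, 1.0)),
        "tr": float(tr),
        "motion": float(rng.lognormal(np.log(0.15), 0.4)),  # mean FD, mm
        "intensity_norm": float(rng.normal(1.0, 0.1)),
    }


def generate_cohort(spec: CohortSpec, with_fc: bool = True,
                    sim_config: SimulationConfig | None = None,
                    params: RwwParameters | None = None,
                    fic_kwargs: dict | None = None) -> list[Subject]:
    """Generate a full cohort of subjects, reproducible under ``spec.seed``.

    Each subject gets an individual connectome drawn from the shared spec, a
    group label, covariates, a subject-specific ground-truth coupling G_true,
    and (for patient groups) a focal tumor perturbation.  With ``with_fc``
    the forward model is run at G_true to attach ground-truth FC.
    """
    rng = np.random.default_rng(spec.seed)
    sim_config = sim_config or SimulationConfig()
    groups = (["CON"] * spec.n_control + ["MEN"] * spec.n_meningioma
              + ["GLI"] * spec.n_glioma)
    n_tr_21 = max(1, round(len(groups) * 11 / 36)) if groups else 0
    subjects: list[Subject] = []
    for idx, group in enumerate(groups):
        sub_seed = derive_seed(spec.seed, idx)
        sub_rng = np.random.default_rng(sub_seed)
        sub_spec = CohortSpec(**{**spec.__dict__, "seed": sub_seed})
        sc, table = generate_sc(sub_spec, rng=sub_rng)
        pert = None
        if group != "CON":
            module = int(sub_rng.integers(spec.n_modules))
            pool = np.flatnonzero(table["module"].to_numpy() == module)
            n_tumor = int(min(len(pool), 1 + sub_rng.poisson(1.0)))
            nodes = tuple(int(v) for v in sub_rng.choice(pool, n_tumor, replace=False))
            # meningioma-like lesions displace (milder weight change) while
            # glioma-like lesions infiltrate (stronger suppression); severity
            # varies per patient, mirroring the order-of-magnitude spread of
            # real lesion volumes
            if group == "MEN":
                wf = float(sub_rng.uniform(0.4, 1.0))
            else:
                wf = float(sub_rng.uniform(0.1, 0.8))
            pert = TumorPerturbation(node_set=nodes, weight_factor=wf,
                                     size_inflation=float(sub_rng.uniform(1.1, 2.5)))
            sc, table = apply_tumor(sc, table, pert)
        tr = 2.1 if idx < n_tr_21 else 2.4
        g_lo, g_hi = spec.g_true_range
        g_true = float(sub_rng.uniform(g_lo, g_hi))
        subj = Subject(
            subject_id=f"sub-{idx:03d}",
            group=group,
            sc=sc,
            region_table=table,
            covariates=_covariates(sub_rng, group, tr),
            g_true=g_true,
            perturbation=pert,
        )
        if with_fc:
            from .neural import tune_fic_feasible

            cfg = SimulationConfig(
                dt=sim_config.dt, duration=sim_config.duration,
                burn_in=sim_config.burn_in, seed=derive_seed(sub_seed, 1),
                record_rates=sim_config.record_rates,
                record_dt=sim_config.record_dt,
            )
            # cap the generative coupling at this connectome's simulable range
            g_used, fic = tune_fic_feasible(
                sc, g_true, params=params, config=cfg, **(fic_kwargs or {}))
            subj.g_true = g_used
            base = params or RwwParameters()
            subj.fc_emp = simulate_fc(sc, base.with_(G=g_used, J=fic.j), cfg, tr)
            subj.j_true = fic.j
        subjects.append(subj)
    return subjects


def covariate_table(subjects: list[Subject]) -> pd.DataFrame:
    """One row per subject: id, group, and all nuisance covariates."""
    rows = []
    for s in subjects:
        rows.append({"subject_id": s.subject_id, "group": s.group, **s.covariates})
    return pd.DataFrame(rows)
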