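"""Synthetic modular cohorts for exercising the full pipeline.

Each group's population covariance is a hierarchical block matrix: unit
diagonal, seven system blocks with within-system correlation
``rho_within``, two nested sub-blocks per system adding ``rho_sub``,
and between-system correlation ``rho_between`` — lowered by
``delta_between`` in the patient-like group, which makes that group's
population network more segregated. Subject time series are stationary
Gaussian draws from the group covariance: Pearson FC depends only on
second-order structure, which is exactly what the NSP measures consume,
so no hemodynamic forward model is attempted.

Covariates mimic the study's shape (49 + 49 subjects, T = 152 volumes,
100 regions) with framewise-displacement means of 0.137 mm
(control-like) and 0.188 mm (patient-like). Symptom scores are wired to
the network by construction: a linear model on one regional measure, or
a U-shaped (quadratic) model on the global balance H_B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fc as fcmod
from . import nsp

__all__ = [
    "SYSTEM_NAMES",
    "LinearScoreModel",
    "QuadraticScoreModel",
    "CohortSpec",
    "Cohort",
    "build_covariance",
    "simulate_subject",
    "generate_cohort",
]

SYSTEM_NAMES = (
    "default",
    "control",
    "dorsal_attention",
    "salient_attention",
    "limbic",
    "motor",
    "visual",
)

_PSD_TOL = -1e-10


@dataclass(frozen=True)
class LinearScoreModel:
    """y = Xz·beta + noise on the z-scored regional ``measure`` features."""

    beta: dict  # region_id -> coefficient (unlisted regions: 0)
    noise_sd: float = 0.5
    measure: str = "HSe"


@dataclass(frozen=True)
class QuadraticScoreModel:
    """U-shaped scores: y = gamma * ((H_B − center) / sd(H_B))² + noise.

    ``center=None`` uses the cohort mean of H_B, putting the vertex in
    the middle of the sampled range; gamma is in score units per
    squared SD of H_B so its default is scale-free.
    """

    gamma: float = 2.0
    center: float | None = None
    noise_sd: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """Study-shaped defaults: 100 regions / 7 systems, T=152, 49+49."""

    n_regions: int = 100
    system_sizes: tuple = (24, 13, 13, 12, 10, 14, 14)
    rho_within: float = 0.35
    rho_sub: float = 0.10
    rho_between: float = 0.15
    delta_between: float = 0.10
    t_len: int = 152
    n_per_group: int = 49
    fd_mean_hc: float = 0.137
    fd_mean_bd: float = 0.188
    fd_sd: float = 0.12
    score_model: object = field(default_factory=QuadraticScoreModel)
    seed: int = 0

    def __post_init__(self):
        if len(self.system_sizes) != 7:
            raise ValueError("exactly 7 system sizes required")
        if sum(self.system_sizes) != self.n_regions:
            raise ValueError("system sizes must sum to n_regions")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if not (0 <= self.rho_between - self.delta_between
                and self.rho_within + self.rho_sub < 1):
            raise ValueError("correlation parameters out of range")

    def region_ids(self) -> list:
        width = len(str(self.n_regions - 1))
        return [f"r{j:0{width}d}" for j in range(self.n_regions)]

    def atlas(self) -> pd.Series:
        labels = np.repeat(SYSTEM_NAMES, self.system_sizes)
        return pd.Series(
            labels, index=pd.Index(self.region_ids(), name="region_id"),
            name="system_name",
        )


@dataclass
class Cohort:
    """One group's simulated subjects plus covariates and scores."""

    group: str
    timeseries: list
    fc: list
    global_measures: pd.DataFrame   # subjects x {HIn, HSe, HB, absHB}
    regional: dict                  # measure -> subjects x regions
    manifest: pd.DataFrame          # subject_id, group, fd, age, sex, score, seed
    covariance: np.ndarray


def build_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Population covariance of one group under the nested block model."""
    g = group.lower()
    if g not in ("hc", "bd"):
        raise ValueError("group must be 'HC' or 'BD'")
    between = spec.rho_between - (spec.delta_between if g == "bd" else 0.0)
    n = spec.n_regions
    cov = np.full((n, n), between)
    start = 0
    for size in spec.system_sizes:
        stop = start + size
        cov[start:stop, start:stop] = spec.rho_within
        half = size // 2
        for lo, hi in ((start, start + half), (start + half, stop)):
            cov[lo:hi, lo:hi] += spec.rho_sub
        start = stop
    np.fill_diagonal(cov, 1.0)
    w, v = np.linalg.eigh(cov)
    if w.min() < _PSD_TOL:
        raise ValueError(
            f"implied covariance is not PSD (min eigenvalue {w.min():.3g})"
        )
    if w.min() < 0:  # numerical dust only: floor and re-symmetrize
        cov = (v * np.clip(w, 0.0, None)) @ v.T
        cov = (cov + cov.T) / 2.0
    return cov


def simulate_subject(cov: np.ndarray, t_len: int, seed,
                     region_ids=None) -> pd.DataFrame:
    """Draw a T x N stationary Gaussian series from ``cov``.

    Uses the symmetric eigenfactorization ``cov^(1/2)``; deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    w, v = np.linalg.eigh(np.asarray(cov, dtype=float))
    root = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    z = rng.standard_normal((t_len, cov.shape[0]))
    x = z @ root
    if region_ids is None:
        region_ids = [str(j) for j in range(cov.shape[0])]
    return pd.DataFrame(x, columns=region_ids)


def _simulate_group(spec, group, cov, seeds, fd_mean, rng, variant):
    ids = spec.region_ids()
    w, v = np.linalg.eigh(cov)
    root = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T  # factor once per group
    ts, fcs, glob, reg_in, reg_se = [], [], [], [], []
    for s in seeds:
        z = np.random.default_rng(s).standard_normal((spec.t_len, cov.shape[0]))
        series = pd.DataFrame(z @ root, columns=ids)
        c = fcmod.compute_fc(series)
        m = nsp.nsp_measures(c, variant=variant)
        ts.append(series)
        fcs.append(c)
        glob.append((m.h_in, m.h_se, m.h_b, m.h_b_abs))
        reg_in.append(m.regional["HIn"].to_numpy())
        reg_se.append(m.regional["HSe"].to_numpy())
    n = len(seeds)
    subj = [f"{group}{i:03d}" for i in range(n)]
    glob_df = pd.DataFrame(glob, columns=["HIn", "HSe", "HB", "absHB"],
                           index=pd.Index(subj, name="subject_id"))
    regional = {
        "HIn": pd.DataFrame(reg_in, index=glob_df.index, columns=ids),
        "HSe": pd.DataFrame(reg_se, index=glob_df.index, columns=ids),
    }
    regional["HB"] = regional["HIn"] - regional["HSe"]
    regional["absHB"] = regional["HB"].abs()
    fd = np.maximum(rng.normal(fd_mean, spec.fd_sd, size=n), 0.0)
    age = rng.normal(33.7, 9.1, size=n)
    sex = (rng.random(n) < 21 / 49).astype(int)
    manifest = pd.DataFrame(
        {"subject_id": subj, "group": group, "fd": fd, "age": age,
         "sex": sex, "seed": list(seeds)}
    ).set_index("subject_id")
    return Cohort(group=group, timeseries=ts, fc=fcs, global_measures=glob_df,
                  regional=regional, manifest=manifest, covariance=cov)


def _attach_scores(spec, hc: Cohort, bd: Cohort, rng) -> None:
    model = spec.score_model
    n_all = len(hc.manifest) + len(bd.manifest)
    if isinstance(model, LinearScoreModel):
        x = pd.concat([hc.regional[model.measure], bd.regional[model.measure]])
        xz = (x - x.mean()) / x.std(ddof=0)
        beta = pd.Series(0.0, index=x.columns)
        beta.update(pd.Series(model.beta))
        y = xz.to_numpy() @ beta.to_numpy()
    elif isinstance(model, QuadraticScoreModel):
        h_b = np.concatenate([hc.global_measures["HB"].to_numpy(),
                              bd.global_measures["HB"].to_numpy()])
        center = h_b.mean() if model.center is None else model.center
        scale = h_b.std(ddof=0)
        y = model.gamma * ((h_b - center) / scale) ** 2
    else:
        raise TypeError("score_model must be Linear- or QuadraticScoreModel")
    y = y + rng.normal(0.0, model.noise_sd, size=n_all)
    hc.manifest["score"] = y[: len(hc.manifest)]
    bd.manifest["score"] = y[len(hc.manifest):]


def generate_cohort(spec: CohortSpec, seed=None,
                    variant: str = "quadratic") -> tuple[Cohort, Cohort]:
    """Simulate the control-like and patient-like cohorts.

    Returns ``(hc, bd)``. All randomness descends from one seed
    (``spec.seed`` unless overridden); per-subject child seeds are
    recorded in the manifests.
    """
    master = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    child = ss.spawn(2 * spec.n_per_group + 2)
    rng_cov = np.random.default_rng(child[-2])  # covariates & scores
    subject_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in child[:-2]]

    cov_hc = build_covariance(spec, "HC")
    cov_bd = build_covariance(spec, "BD")
    hc = _simulate_group(spec, "HC", cov_hc,
                         subject_seeds[: spec.n_per_group],
                         spec.fd_mean_hc, rng_cov, variant)
    bd = _simulate_group(spec, "BD", cov_bd,
                         subject_seeds[spec.n_per_group:],
                         spec.fd_mean_bd, rng_cov, variant)
    _attach_scores(spec, hc, bd, rng_cov)
    return hc, bd
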