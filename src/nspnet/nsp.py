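"""Nested-spectral-partition (NSP) measures of segregation and integration.

The FC matrix ``C`` is eigendecomposed as ``C = U Λ Uᵀ`` with eigenmodes
ordered by descending eigenvalue (small negative eigenvalues clipped to
zero). Successive eigenvectors then split the network recursively: the
first mode — uniform in sign for a strictly positive matrix by
Perron–Frobenius — defines one whole-brain module; at every deeper level
each existing module is divided into the positive-sign and negative-sign
members of the next eigenvector (modules whose members share a sign stay
intact). The partition at level ``i`` has ``M_i`` modules of sizes
``m_j`` and is scored by

    H_i = Λ_i² · M_i · (1 − p_i) / N,

where ``p_i = Σ_j |m_j − N/M_i| / N`` penalizes deviation from equal
module sizes. Level 1 measures global integration, the remaining levels
segregation:

    H_In = H_1 / N,   H_Se = Σ_{i≥2} H_i / N,   H_B = H_In − H_Se,

and the same components map onto regions through the squared
eigenvector entries: ``H_In^j = H_1 U_1j²``, ``H_Se^j = Σ_{i≥2} H_i U_ij²``.
``H_B`` near zero marks a balanced network; ``|H_B|`` measures the
deviation from that balance.

The flattened-equation ambiguity between Λ_i² and Λ_i is exposed as the
``variant`` switch ("quadratic", the default, vs "linear"); every
conservation identity holds under either.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EigenDecomposition",
    "NestedPartition",
    "NSPMeasures",
    "decompose_fc",
    "nested_partition",
    "level_measures",
    "global_measures",
    "regional_measures",
    "system_aggregate",
    "nsp_measures",
    "write_measures",
]

#: entries of an eigenvector smaller than this in magnitude count as sign ties
#: and are grouped with the positive side of a split
SIGN_TIE_TOL = 1e-12

_SYMMETRY_TOL = 1e-8


@dataclass(frozen=True)
class EigenDecomposition:
    """Eigenmodes of an FC matrix, descending, negatives clipped to zero."""

    lambdas: np.ndarray  # (N,) eigenvalues, Λ_1 ≥ … ≥ Λ_N ≥ 0
    vectors: np.ndarray  # (N, N) orthonormal columns, column i ↔ Λ_i


@dataclass(frozen=True)
class NestedPartition:
    """Module labels per level; level i+1 refines level i."""

    labels: np.ndarray  # (N levels, N regions) integer module labels
    module_counts: np.ndarray  # (N,) M_i per level

    def module_sizes(self, level: int) -> np.ndarray:
        """Sizes m_j of the modules at ``level`` (0-based)."""
        return np.bincount(self.labels[level])


@dataclass
class NSPMeasures:
    """Global, per-level, regional and (optionally) system-level measures."""

    h: np.ndarray          # per-level H_i
    p: np.ndarray          # per-level size-correction p_i
    h_in: float
    h_se: float
    h_b: float
    h_b_abs: float
    regional: pd.DataFrame              # columns HIn, HSe, HB, absHB
    per_system: pd.DataFrame | None = field(default=None)


def decompose_fc(fc) -> EigenDecomposition:
    """Eigendecompose an FC matrix, ordering modes by descending eigenvalue.

    Negative eigenvalues (small, from the zeroing of negative edges) are
    clipped to zero after sorting. Each eigenvector's sign is fixed so
    its largest-magnitude entry is positive; within degenerate
    eigenspaces the basis itself remains solver-dependent.
    """
    c = np.asarray(fc, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("FC matrix must be square")
    if not np.allclose(c, c.T, atol=_SYMMETRY_TOL):
        raise ValueError("FC matrix must be symmetric")
    lam, u = np.linalg.eigh((c + c.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    u = u[:, order]
    lam = np.clip(lam, 0.0, None)
    # canonical sign: largest |entry| of each column positive
    peak = np.argmax(np.abs(u), axis=0)
    flip = np.sign(u[peak, np.arange(u.shape[1])])
    flip[flip == 0] = 1.0
    u = u * flip
    return EigenDecomposition(lambdas=lam, vectors=u)


def nested_partition(eig: EigenDecomposition) -> NestedPartition:
    """Split modules recursively by the signs of successive eigenvectors.

    Level 1 is the whole network; at level i ≥ 2 every module of level
    i−1 is divided into its positive- and negative-sign members under
    eigenvector i (entries within ``SIGN_TIE_TOL`` of zero join the
    positive side). A module whose members all share one sign is kept.
    All N levels are produced even after every module is a singleton.
    """
    u = eig.vectors
    n = u.shape[0]
    labels = np.zeros((n, n), dtype=np.int64)
    counts = np.ones(n, dtype=np.int64)
    current = np.zeros(n, dtype=np.int64)
    for level in range(1, n):
        neg = u[:, level] < -SIGN_TIE_TOL  # ties go to the positive side
        # encode (parent module, side); unique-relabel keeps parents grouped,
        # positive side first, so each parent is preserved or split in two
        key = current * 2 + neg
        _, current = np.unique(key, return_inverse=True)
        current = current.astype(np.int64)
        labels[level] = current
        counts[level] = current.max() + 1
    return NestedPartition(labels=labels, module_counts=counts)


def level_measures(
    eig: EigenDecomposition,
    partition: NestedPartition,
    variant: str = "quadratic",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level H_i and module-size corrections p_i.

    ``variant="quadratic"`` uses Λ_i² in H_i (default); ``"linear"``
    uses Λ_i. Levels with a clipped (zero) eigenvalue score H_i = 0.
    """
    if variant not in ("quadratic", "linear"):
        raise ValueError("variant must be 'quadratic' or 'linear'")
    lam = eig.lambdas
    n = lam.shape[0]
    p = np.empty(n)
    h = np.empty(n)
    for i in range(n):
        sizes = partition.module_sizes(i)
        m_i = partition.module_counts[i]
        p[i] = np.abs(sizes - n / m_i).sum() / n
        lam_term = lam[i] ** 2 if variant == "quadratic" else lam[i]
        h[i] = lam_term * m_i * (1.0 - p[i]) / n
    return h, p


def global_measures(h: np.ndarray) -> tuple[float, float, float, float]:
    """(H_In, H_Se, H_B, |H_B|) from the per-level H_i vector."""
    n = h.shape[0]
    h_in = float(h[0] / n)
    h_se = float(h[1:].sum() / n)
    h_b = h_in - h_se
    return h_in, h_se, h_b, abs(h_b)


def regional_measures(
    eig: EigenDecomposition, h: np.ndarray, region_ids=None
) -> pd.DataFrame:
    """Map integration/segregation onto regions via squared eigenvector entries."""
    u2 = eig.vectors**2
    h_in_j = h[0] * u2[:, 0]
    h_se_j = u2[:, 1:] @ h[1:]
    h_b_j = h_in_j - h_se_j
    if region_ids is None:
        region_ids = [str(j) for j in range(u2.shape[0])]
    return pd.DataFrame(
        {
            "HIn": h_in_j,
            "HSe": h_se_j,
            "HB": h_b_j,
            "absHB": np.abs(h_b_j),
        },
        index=pd.Index(region_ids, name="region_id"),
    )


def system_aggregate(regional: pd.DataFrame, atlas: pd.Series) -> pd.DataFrame:
    """Unweighted mean of each regional measure over each system's regions."""
    missing = regional.index.difference(atlas.index)
    if len(missing):
        raise ValueError(
            f"regions missing from atlas mapping: {list(map(str, missing[:5]))}"
        )
    systems = atlas.reindex(regional.index)
    out = regional.groupby(systems.values).mean()
    out.index.name = "system_name"
    return out


def nsp_measures(
    fc,
    atlas: pd.Series | None = None,
    variant: str = "quadratic",
) -> NSPMeasures:
    """Full NSP chain: decompose, partition, score, map to regions/systems."""
    fc_df = fc if isinstance(fc, pd.DataFrame) else None
    eig = decompose_fc(fc)
    part = nested_partition(eig)
    h, p = level_measures(eig, part, variant=variant)
    h_in, h_se, h_b, h_b_abs = global_measures(h)
    regional = regional_measures(
        eig, h, region_ids=None if fc_df is None else fc_df.index
    )
    per_system = None if atlas is None else system_aggregate(regional, atlas)
    return NSPMeasures(
        h=h,
        p=p,
        h_in=h_in,
        h_se=h_se,
        h_b=h_b,
        h_b_abs=h_b_abs,
        regional=regional,
        per_system=per_system,
    )


def write_measures(measures: NSPMeasures, subject_id: str, path) -> None:
    """Long-format TSV: subject_id, scale, name, measure, value."""
    rows = []
    for meas, val in (
        ("HIn", measures.h_in),
        ("HSe", measures.h_se),
        ("HB", measures.h_b),
        ("absHB", measures.h_b_abs),
    ):
        rows.append((subject_id, "global", "whole_brain", meas, val))
    for region, row in measures.regional.iterrows():
        for meas in ("HIn", "HSe", "HB", "absHB"):
            rows.append((subject_id, "region", region, meas, row[meas]))
    if measures.per_system is not None:
        for system, row in measures.per_system.iterrows():
            for meas in ("HIn", "HSe", "HB", "absHB"):
                rows.append((subject_id, "system", system, meas, row[meas]))
    pd.DataFrame(
        rows, columns=["subject_id", "scale", "name", "measure", "value"]
    ).to_csv(path, sep="\t", index=False)
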