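"""Exposure times, connectivity matrices and their dissimilarity form.

The accumulated space–time integral Phi[i, j] of each tracer is turned
into an exposure time by normalising with the initial tracer amount,

    T[i, j] = Phi[i, j] / ∫_{Ω_i} φ(0) dΩ = Phi[i, j] / A_i   (days),

the duration material from subdomain i spends inside subdomain j,
counting re-entries — hence always ≥ the residence time.  The
connectivity matrix then expresses a relative transit probability per
unit target area over a dispersal time scale τ,

    P[i, j] = T[i, j] / (A_j · τ)                              (m⁻²).

P is asymmetric and not a metric; for ordination it is symmetrised and
max-scaled into a dissimilarity in [0, 1].  That transform is this
package's choice (recorded in output metadata), not a canonical one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracer_transport import ExposureAccumulator

__all__ = [
    "ExposureMatrix",
    "ConnectivityMatrix",
    "exposure_time",
    "connectivity_matrix",
    "replacement_fraction",
    "connectivity_to_dissimilarity",
    "DISSIMILARITY_TRANSFORM",
]

#: Identifier of the connectivity→dissimilarity transform, recorded in
#: metadata sidecars so users know which convention produced a file.
DISSIMILARITY_TRANSFORM = "symmetrize-mean+max-scale(1-S/Smax)"


@dataclass(frozen=True)
class ExposureMatrix:
    """Domain-to-domain exposure times T[i, j] in days."""

    T: np.ndarray
    labels: list[str]
    source_areas: np.ndarray
    horizon: float

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        if not np.isfinite(T).all() or (T < 0).any():
            raise ValueError("exposure times must be finite and non-negative")
        object.__setattr__(self, "T", T)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Connectivity probabilities per target area, P[i, j] (m⁻²)."""

    P: np.ndarray
    labels: list[str]
    tau: float
    target_areas: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if not np.isfinite(P).all() or (P < 0).any():
            raise ValueError("connectivity entries must be finite and non-negative")
        object.__setattr__(self, "P", P)


def exposure_time(
    acc: ExposureAccumulator, source_areas: np.ndarray | None = None
) -> ExposureMatrix:
    """Normalise accumulated Phi by the initial tracer amount per source.

    The initial amount of tracer i is its source area A_i (initial value
    1 over Ω_i in the depth-integrated convention), so
    T[i, j] = Phi[i, j] / A_i, in days.
    """
    if source_areas is None:
        source_areas = acc.source_areas
    source_areas = np.asarray(source_areas, dtype=float)
    if (source_areas <= 0).any():
        raise ValueError("all source areas must be positive")
    T = acc.Phi / source_areas[:, None]
    return ExposureMatrix(
        T=T, labels=list(acc.labels), source_areas=source_areas, horizon=acc.t_end
    )


def connectivity_matrix(
    exposure: ExposureMatrix, areas: np.ndarray, tau: float
) -> ConnectivityMatrix:
    """P[i, j] = T[i, j] / (A_j · τ), the transit probability per target area."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    areas = np.asarray(areas, dtype=float)
    if (areas <= 0).any():
        raise ValueError("all target areas must be positive")
    P = exposure.T / (areas[None, :] * tau)
    return ConnectivityMatrix(
        P=P, labels=list(exposure.labels), tau=tau, target_areas=areas
    )


def replacement_fraction(t_exposure: float, elapsed: float) -> float:
    """Fraction of a well-mixed domain's water replaced after ``elapsed`` days.

    Interprets the subdomain exposure time as the e-folding time of
    exponential flushing: fraction = 1 − exp(−elapsed / t_exposure).
    An exposure time of 1.1 d implies > 99 % replacement within a week.
    This is an interpretive device, separate from the exposure-time
    definition itself.
    """
    if t_exposure <= 0:
        raise ValueError(f"t_exposure must be positive, got {t_exposure}")
    if elapsed < 0:
        raise ValueError(f"elapsed must be non-negative, got {elapsed}")
    return 1.0 - float(np.exp(-elapsed / t_exposure))


def connectivity_to_dissimilarity(conn: ConnectivityMatrix):
    """Turn the asymmetric connectivity matrix into a [0, 1] dissimilarity.

    S = (P + Pᵀ)/2 is symmetrised connectivity; D = 1 − S/max(S) with a
    forced zero diagonal.  Strong connections map to small distances.
    Returns a :class:`~oceanconn.community_stats.DissimilarityMatrix`.
    """
    from .community_stats import DissimilarityMatrix

    P = conn.P
    S = 0.5 * (P + P.T)
    smax = S.max()
    if smax <= 0:
        raise ValueError("connectivity matrix is all zero; dissimilarity undefined")
    D = 1.0 - S / smax
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(D=D, labels=list(conn.labels))
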