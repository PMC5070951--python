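"""Parcel metadata: parcellation maps, functional systems, mixing quality.

A parcel is the unit of analysis — a labeled cortical region whose time
series the pipeline couples and tests.  Analyses run on a fine
parcellation and are collapsed to a coarser one for group statistics;
each coarse parcel belongs to one of (by default) seven functional
systems.  Source reconstruction mixes signals between nearby parcels;
per-parcel quality metrics summarize that mixing:

fidelity f
    phase correlation of a parcel's reconstructed series with its own
    true series (reconstruction accuracy),
cross-talk c
    mean phase correlation of the reconstructed series with the true
    series of *other* parcels (contamination received),
spread s
    mean phase correlation of other parcels' reconstructions with this
    parcel's true series (contamination emitted).

Low-fidelity, high-mixing parcels are excluded from graphs.  The full
pairwise cross-talk matrix is retained because edge bundling measures
the proximity of two edges in mixing space by products of pairwise
cross-talk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParcelMeta", "meta_from_mixing"]

N_SYSTEMS_DEFAULT = 7


@dataclass
class ParcelMeta:
    """Parcellation membership, system labels and mixing-quality metrics.

    All per-parcel arrays are indexed by the *fine* parcel index.
    ``fine_to_coarse`` maps every fine parcel to exactly one coarse
    parcel; ``coarse_to_system`` maps every coarse parcel to exactly one
    functional system.
    """

    fine_to_coarse: np.ndarray
    coarse_to_system: np.ndarray
    fidelity: np.ndarray
    cross_talk: np.ndarray
    spread: np.ndarray
    excluded: np.ndarray
    crosstalk_matrix: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.fine_to_coarse = np.asarray(self.fine_to_coarse, dtype=int)
        self.coarse_to_system = np.asarray(self.coarse_to_system, dtype=int)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        n = self.n_fine
        if self.crosstalk_matrix is None:
            self.crosstalk_matrix = np.eye(n)
        if not (len(self.fidelity) == len(self.cross_talk) == len(self.spread) == n):
            raise ValueError("per-parcel metric lengths disagree")
        if self.fine_to_coarse.min() < 0 or self.fine_to_coarse.max() >= self.n_coarse:
            raise ValueError("fine_to_coarse references an unmapped coarse parcel")

    @property
    def n_fine(self) -> int:
        return len(self.fine_to_coarse)

    @property
    def n_coarse(self) -> int:
        return len(self.coarse_to_system)

    @property
    def n_systems(self) -> int:
        return int(self.coarse_to_system.max()) + 1

    def quality(self) -> np.ndarray:
        """Reconstruction quality score f / (c * s); low scores are excluded."""
        denom = self.cross_talk * self.spread
        with np.errstate(divide="ignore"):
            return np.where(denom > 0, self.fidelity / denom, np.inf)

    def apply_exclusion(self, fraction: float = 0.10) -> None:
        """Exclude the lowest-quality ``fraction`` of parcels (in place)."""
        if not 0 <= fraction < 1:
            raise ValueError("fraction must be in [0, 1)")
        n_drop = int(round(fraction * self.n_fine))
        if n_drop == 0:
            self.excluded[:] = False
            return
        order = np.argsort(self.quality(), kind="stable")
        self.excluded[:] = False
        self.excluded[order[:n_drop]] = True

    def included_fine(self) -> np.ndarray:
        return np.flatnonzero(~self.excluded)

    @staticmethod
    def identity(n_parcels: int, n_systems: int = N_SYSTEMS_DEFAULT) -> "ParcelMeta":
        """Trivial metadata: fine == coarse, systems assigned round-robin."""
        return ParcelMeta(
            fine_to_coarse=np.arange(n_parcels),
            coarse_to_system=np.arange(n_parcels) % n_systems,
            fidelity=np.ones(n_parcels),
            cross_talk=np.full(n_parcels, 1e-3),
            spread=np.full(n_parcels, 1e-3),
            excluded=np.zeros(n_parcels, dtype=bool),
            crosstalk_matrix=np.eye(n_parcels),
        )


def meta_from_mixing(
    mixing: np.ndarray,
    n_coarse: int | None = None,
    n_systems: int = N_SYSTEMS_DEFAULT,
) -> ParcelMeta:
    """Derive parcel metadata from a known linear mixing matrix.

    For row-normalized mixing weights M (reconstructed_p = sum_q M[p,q]
    true_q) over unit-variance independent sources, the correlation of
    reconstruction p with true source q is M[p,q] / ||M[p,:]||; fidelity,
    cross-talk and spread follow from their definitions.  The symmetric
    pairwise cross-talk matrix (unit diagonal) feeds edge bundling.
    """
    mixing = np.asarray(mixing, dtype=float)
    if mixing.ndim != 2 or mixing.shape[0] != mixing.shape[1]:
        raise ValueError("mixing matrix must be square")
    n = mixing.shape[0]
    row_norm = np.linalg.norm(mixing, axis=1, keepdims=True)
    corr = mixing / np.where(row_norm > 0, row_norm, 1.0)  # corr[p, q]
    fidelity = np.diag(corr).copy()
    off = corr.copy()
    np.fill_diagonal(off, np.nan)
    cross_talk = np.nanmean(off, axis=1)  # received by p
    spread = np.nanmean(off, axis=0)  # emitted by p
    ct = (corr + corr.T) / 2.0
    np.fill_diagonal(ct, 1.0)
    if n_coarse is None:
        n_coarse = n
    group = n // n_coarse
    fine_to_coarse = np.minimum(np.arange(n) // max(group, 1), n_coarse - 1)
    return ParcelMeta(
        fine_to_coarse=fine_to_coarse,
        coarse_to_system=np.arange(n_coarse) % n_systems,
        fidelity=fidelity,
        cross_talk=np.maximum(cross_talk, 1e-12),
        spread=np.maximum(spread, 1e-12),
        excluded=np.zeros(n, dtype=bool),
        crosstalk_matrix=np.clip(ct, 0.0, 1.0),
    )
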