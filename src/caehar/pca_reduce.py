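"""PCA reduction of extracted features.

Default ("pooled") mode acts on the 45-channel axis: every 630-feature row
is viewed as a 14 x 45 block, all blocks are pooled into one set of 45-dim
observations, and a single covariance eigendecomposition yields the basis.
Projecting onto the top ``n_keep`` (default 3) eigenvectors reduces each
segment to 14 x 3 = 42 values.  A "flat" mode treating rows as plain
630-dim vectors is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCABasis", "fit_pca", "contribution_rates", "project"]

N_FEATURE_TYPES = 14
N_CHANNEL_AXIS = 45


@dataclass
class PCABasis:
    """Eigendecomposition of the pooled feature covariance.

    ``eigenvectors`` holds unit-norm eigenvectors as columns, matching the
    descending order of ``eigenvalues``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    contributions: np.ndarray
    center: np.ndarray
    n_keep: int = 3
    mode: str = "pooled"

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.contributions)


def contribution_rates(eigenvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Each eigenvalue's share of the total, plus cumulative sums."""
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(ev < 0):
        # tolerate tiny negative round-off from eigh
        if np.any(ev < -1e-10 * max(1.0, float(np.max(np.abs(ev))))):
            raise ValueError("negative eigenvalues")
        ev = np.clip(ev, 0.0, None)
    total = float(ev.sum())
    if total == 0.0:
        raise ValueError("all eigenvalues are zero")
    props = ev / total
    return props, np.cumsum(props)


def _pool(features: np.ndarray, n_channels: int) -> np.ndarray:
    n, width = features.shape
    if width % n_channels != 0:
        raise ValueError(
            f"feature width {width} is not a multiple of {n_channels}")
    return features.reshape(n * (width // n_channels), n_channels)


def fit_pca(features: np.ndarray, n_keep: int = 3, mode: str = "pooled",
            n_channels: int = N_CHANNEL_AXIS) -> PCABasis:
    """Fit the reduction basis on a (segments x 630) feature matrix.

    ``n_channels`` sets the pooled channel-axis width; the default matches
    the full 45-channel sensor layout, channel subsets pass their own.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[0] < 2:
        raise ValueError("need at least 2 feature rows")
    if mode == "pooled":
        obs = _pool(F, n_channels)
    elif mode == "flat":
        obs = F
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not (1 <= n_keep <= obs.shape[1]):
        raise ValueError("n_keep out of range")
    center = obs.mean(axis=0)
    cov = np.cov(obs - center, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    props, _ = contribution_rates(evals)
    return PCABasis(eigenvalues=evals, eigenvectors=evecs,
                    contributions=props, center=center,
                    n_keep=n_keep, mode=mode)


def project(features: np.ndarray, basis: PCABasis) -> np.ndarray:
    """Project feature rows onto the retained components.

    Pooled mode maps each 14 x 45 block to 14 x ``n_keep`` and flattens
    feature-major, so the default basis turns 630 into 42 values per row.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    Vk = basis.eigenvectors[:, :basis.n_keep]
    if basis.mode == "flat":
        if F.shape[1] != basis.center.shape[0]:
            raise ValueError("feature width does not match basis")
        return (F - basis.center) @ Vk
    n, width = F.shape
    n_channels = basis.center.shape[0]
    if width % n_channels != 0:
        raise ValueError("feature width is not a multiple of the channel axis")
    blocks = F.reshape(n, width // n_channels, n_channels)
    proj = (blocks - basis.center) @ Vk
    return proj.reshape(n, -1)
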