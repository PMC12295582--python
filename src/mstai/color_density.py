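"""Per-image color density estimation in normalized RGB space.

A skin color is not one RGB point but a cloud of pixels in the RGB cube;
this module models that cloud with a variational Bayesian Gaussian
mixture (VB-GMM) fitted independently per image.  The variational
treatment places priors over the mixture parameters, so surplus
components shrink away on their own and the fixed component budget
(default 8) acts as an upper bound rather than a hard model choice.

Pixels are mapped to [0, 1]^3 by dividing by 255; every density in the
package lives in that space, so the scaling Jacobian cancels in all
comparisons.  Log-densities are evaluated with log-sum-exp over
per-component Gaussian log-pdfs and never under- or overflow for valid
covariances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.mixture import BayesianGaussianMixture

from ._validate import as_mask, as_rgb_image
from .errors import ExclusionError, ValidationError

#: Ridge added to a covariance whose smallest eigenvalue falls below it;
#: keeps flat swatch clouds (spread -> 0) evaluable.
COV_REGULARIZATION = 1e-6

#: Pixel clouds above this size are subsampled (seeded) before fitting.
SUBSAMPLE_CAP = 100_000


@dataclass
class PixelCloud:
    """Points in [0, 1]^3 with a provenance tag."""

    points: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(f"points: expected shape (n, 3), got {pts.shape}")
        if pts.size and (pts.min() < -1e-9 or pts.max() > 1 + 1e-9):
            raise ValidationError("points: coordinates must lie in [0, 1]")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MixtureDensity:
    """A Gaussian mixture density f(x) = sum_k w_k N(x | mu_k, Sigma_k).

    Weights sum to one; covariances are regularized to be symmetric
    positive definite on construction, so ``log_density`` is finite
    everywhere.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        cov = np.asarray(self.covariances, dtype=float)
        if w.ndim != 1 or mu.shape != (len(w), 3) or cov.shape != (len(w), 3, 3):
            raise ValidationError("weights/means/covariances: inconsistent shapes")
        if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("weights: must be nonnegative and sum to 1 within 1e-9")
        cov = 0.5 * (cov + np.swapaxes(cov, 1, 2))
        for k in range(len(w)):
            if np.linalg.eigvalsh(cov[k]).min() < COV_REGULARIZATION:
                cov[k] = cov[k] + COV_REGULARIZATION * np.eye(3)
        self.weights = np.clip(w, 0.0, None)
        self.weights = self.weights / self.weights.sum()
        self.means = mu
        self.covariances = cov
        self._chol = np.linalg.cholesky(cov)
        self._log_norm = -(
            1.5 * np.log(2.0 * np.pi)
            + np.log(np.diagonal(self._chol, axis1=1, axis2=2)).sum(axis=1)
        )

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def component_log_densities(self, points: np.ndarray) -> np.ndarray:
        """Per-component Gaussian log-pdfs, shape (n_points, K)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty((len(pts), self.n_components))
        for k in range(self.n_components):
            diff = (pts - self.means[k]).T
            z = solve_triangular(self._chol[k], diff, lower=True)
            out[:, k] = self._log_norm[k] - 0.5 * (z**2).sum(axis=0)
        return out

    def log_density(self, points: np.ndarray) -> np.ndarray:
        """log f(x) via log-sum-exp; finite for any finite input."""
        comp = self.component_log_densities(points)
        with np.errstate(divide="ignore"):
            logw = np.where(self.weights > 0, np.log(np.clip(self.weights, 1e-300, None)), -np.inf)
        return logsumexp(comp + logw[None, :], axis=1)

    def density(self, points: np.ndarray) -> np.ndarray:
        return np.exp(self.log_density(points))

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureDensity":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            covariances=np.asarray(d["covariances"], dtype=float),
            metadata=d.get("metadata", {}),
        )


def extract_skin_pixels(
    image: np.ndarray, frame_mask: np.ndarray, lesion_mask: np.ndarray
) -> PixelCloud:
    """Pixels outside both the frame and the lesion, normalized to [0, 1]^3."""
    image = as_rgb_image(image)
    frame_mask = as_mask(frame_mask, "frame_mask", image.shape[:2])
    lesion_mask = as_mask(lesion_mask, "lesion_mask", image.shape[:2])
    skin = ~(frame_mask | lesion_mask)
    if not skin.any():
        raise ExclusionError("excluded: insufficient skin area")
    return PixelCloud(points=image[skin].astype(float) / 255.0, source="skin")


def fit_vbgmm(
    cloud: PixelCloud | np.ndarray,
    n_components: int = 8,
    seed: int = 0,
    max_iter: int = 500,
    subsample_cap: int = SUBSAMPLE_CAP,
) -> MixtureDensity:
    """Fit a VB-GMM to a pixel cloud.

    ``n_components`` caps the number of components; the Dirichlet-process
    weight prior (concentration 1/K) lets the fit use fewer.  Clouds
    larger than ``subsample_cap`` are subsampled with a seed derived from
    ``seed`` so repeated fits are identical.
    """
    pts = cloud.points if isinstance(cloud, PixelCloud) else PixelCloud(cloud).points
    if len(pts) < n_components:
        raise ValidationError(
            f"cloud: {len(pts)} points is fewer than n_components={n_components}; "
            "consider provider mode 'none' or excluding the image"
        )
    if len(pts) > subsample_cap:
        idx = np.random.default_rng(seed).choice(len(pts), size=subsample_cap, replace=False)
        pts = pts[idx]
    model = BayesianGaussianMixture(
        n_components=n_components,
        covariance_type="full",
        weight_concentration_prior_type="dirichlet_process",
        weight_concentration_prior=1.0 / n_components,
        reg_covar=COV_REGULARIZATION,
        max_iter=max_iter,
        random_state=int(seed) % (2**31),
        n_init=1,
    )
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning

    with _warnings.catch_warnings():
        # a non-converged variational fit is still a valid density; the
        # converged flag is recorded in the metadata instead
        _warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(pts)
    return MixtureDensity(
        weights=model.weights_,
        means=model.means_,
        covariances=model.covariances_,
        metadata={
            "n_points": int(len(pts)),
            "n_components": int(n_components),
            "seed": int(seed),
            "converged": bool(model.converged_),
        },
    )


def log_density(density: MixtureDensity, points: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`MixtureDensity.log_density`."""
    return density.log_density(points)
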