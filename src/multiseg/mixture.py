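"""Multichannel tissue classification with per-class Gaussian mixtures.

The generative model follows the multispectral "unified segmentation" family:
each tissue class c (gray matter, white matter, CSF, ...) emits the N-channel
intensity vector x of its voxels from a mixture of multivariate Gaussians

    p(x | c) = sum_j w_cj N(x; mu_cj, Sigma_cj),

combined with either stationary class proportions pi_c or user-supplied
spatial prior volumes pi_c(v).  Fitting is plain EM on the observed-data
log-likelihood with log-sum-exp stabilisation; an optional smooth
multiplicative bias field per channel (polynomial in normalised voxel
coordinates, on the log-intensity scale) is re-estimated each iteration by
responsibility-weighted least squares.  No spatial regularisation and no
registration: priors, when given, must already live on the data grid.

Two entry points:

* :class:`MultichannelMixture` / :class:`MixtureResults` — model object built
  from a :class:`~multiseg.volumes.ChannelStack`, ``fit()`` returns results
  carrying the fitted density model, the likelihood trace, posterior tissue
  probability maps and a ``summary()`` table.
* functional wrappers :func:`init_model`, :func:`em_fit`,
  :func:`posterior_maps`, :func:`segment` over the same core.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cholesky, eigh
from scipy.special import logsumexp

from .volumes import ChannelStack, Volume, check_grid, write_volume

logger = logging.getLogger(__name__)

PRIOR_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GaussianComponent:
    """One multivariate Gaussian of a class mixture."""

    mean: np.ndarray
    covariance: np.ndarray
    weight: float

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match mean dimension")
        if not (0 < self.weight <= 1 + 1e-12):
            raise ValueError(f"component weight must be in (0, 1], got {self.weight}")

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class ClassSpec:
    """A tissue class and how many Gaussians model its intensity density."""

    name: str
    n_components: int = 1

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


#: GM and WM as single Gaussians, CSF as a 2-mixture (its compartment is
#: heterogeneous), plus an OTHER class absorbing dura, vessels, connective
#: tissue and any residual background inside the mask.
DEFAULT_CLASS_SPECS = (
    ClassSpec("GM", 1),
    ClassSpec("WM", 1),
    ClassSpec("CSF", 2),
    ClassSpec("OTHER", 2),
)


@dataclass
class TissueModel:
    """Fitted (or initial) per-class Gaussian-mixture density model."""

    class_specs: list[ClassSpec]
    components: list[list[GaussianComponent]]
    channel_names: list[str]
    stationary_priors: np.ndarray | None = None
    prior_volumes: list[Volume] | None = None
    bias_order: int = 0
    bias_coefficients: np.ndarray | None = None  # (n_basis, n_channels)
    scaling: dict | None = None
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.class_specs) != len(self.components):
            raise ValueError("one component list per class required")
        for spec, comps in zip(self.class_specs, self.components):
            if len(comps) != spec.n_components:
                raise ValueError(f"class {spec.name}: component count mismatch")
            total = sum(c.weight for c in comps)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"class {spec.name}: component weights sum to {total}, not 1"
                )
        if self.stationary_priors is not None:
            self.stationary_priors = np.asarray(self.stationary_priors, dtype=float)
            if abs(self.stationary_priors.sum() - 1.0) > 1e-9:
                raise ValueError("stationary class priors must sum to 1")

    @property
    def n_classes(self) -> int:
        return len(self.class_specs)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def class_names(self) -> list[str]:
        return [s.name for s in self.class_specs]

    def class_components(self, name: str) -> list[GaussianComponent]:
        return self.components[self.class_names.index(name)]

    def representative(self, name: str) -> GaussianComponent:
        """The component with largest within-class weight (ties: first)."""
        comps = self.class_components(name)
        return comps[int(np.argmax([c.weight for c in comps]))]

    def class_mean(self, name: str) -> np.ndarray:
        """Weight-averaged mean of a class's mixture (its density centroid)."""
        comps = self.class_components(name)
        return np.sum([c.weight * c.mean for c in comps], axis=0)

    # -- flat parameter views used by the EM core --------------------------
    def _flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        means, covs, weights, class_of = [], [], [], []
        for ci, comps in enumerate(self.components):
            for c in comps:
                means.append(c.mean)
                covs.append(c.covariance)
                weights.append(c.weight)
                class_of.append(ci)
        return (
            np.array(means), np.array(covs),
            np.array(weights), np.array(class_of, dtype=int),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "channel_names": self.channel_names,
            "classes": [
                {
                    "name": spec.name,
                    "n_components": spec.n_components,
                    "components": [
                        {
                            "weight": float(c.weight),
                            "mean": c.mean.tolist(),
                            "covariance": c.covariance.tolist(),
                        }
                        for c in comps
                    ],
                }
                for spec, comps in zip(self.class_specs, self.components)
            ],
            "class_priors": {
                "mode": "spatial" if self.prior_volumes is not None else "stationary",
                "proportions": (
                    self.stationary_priors.tolist()
                    if self.stationary_priors is not None else None
                ),
            },
            "bias": {
                "order": int(self.bias_order),
                "coefficients": (
                    self.bias_coefficients.tolist()
                    if self.bias_coefficients is not None else None
                ),
            },
            "scaling": self.scaling,
            "seed": self.seed,
            "config": self.config,
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TissueModel":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            obj = json.loads(Path(source).read_text())
        else:
            obj = json.loads(source)
        specs = [ClassSpec(c["name"], c["n_components"]) for c in obj["classes"]]
        comps = [
            [
                GaussianComponent(
                    np.array(k["mean"]), np.array(k["covariance"]), k["weight"]
                )
                for k in c["components"]
            ]
            for c in obj["classes"]
        ]
        props = obj["class_priors"]["proportions"]
        bias = obj.get("bias", {})
        coef = bias.get("coefficients")
        return cls(
            class_specs=specs,
            components=comps,
            channel_names=obj["channel_names"],
            stationary_priors=np.array(props) if props is not None else None,
            prior_volumes=None,
            bias_order=int(bias.get("order", 0)),
            bias_coefficients=np.array(coef) if coef is not None else None,
            scaling=obj.get("scaling"),
            seed=obj.get("seed"),
            config=obj.get("config", {}),
        )


@dataclass
class TissueProbabilityMaps:
    """Per-class posterior probability volumes; sums to 1 inside the mask."""

    maps: list[Volume]
    class_names: list[str]

    def __post_init__(self) -> None:
        if len(self.maps) != len(self.class_names):
            raise ValueError("one map per class name required")
        ref = self.maps[0]
        for m in self.maps[1:]:
            check_grid(ref, m)

    @property
    def grid(self) -> Volume:
        return self.maps[0]

    def get(self, name: str) -> Volume:
        return self.maps[self.class_names.index(name)]

    def total(self) -> np.ndarray:
        return np.sum([m.data for m in self.maps], axis=0)

    def to_files(self, outdir: str | Path, prefix: str = "tpm") -> dict[str, str]:
        outdir = Path(outdir)
        out = {}
        for name, vol in zip(self.class_names, self.maps):
            out[name] = str(
                write_volume(vol, outdir / f"{prefix}_{name.lower()}.nii.gz")
            )
        # stacked 4D convenience output
        import nibabel as nib

        stacked = np.stack([m.data for m in self.maps], axis=-1).astype(np.float32)
        p4 = outdir / f"{prefix}_all.nii.gz"
        nib.save(nib.Nifti1Image(stacked, self.grid.affine), str(p4))
        out["__4d__"] = str(p4)
        return out


@dataclass
class FitTrace:
    """Per-iteration observed-data log-likelihood and convergence record.

    ``interventions`` lists the trace indices immediately following a
    starved-component re-seed; EM ascent restarts there, so monotonicity is
    asserted within the segments between interventions.
    """

    log_likelihood: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    seed: int | None = None
    interventions: list[int] = field(default_factory=list)

    def is_monotone(self, rtol: float = 1e-8) -> bool:
        ll = np.asarray(self.log_likelihood)
        if ll.size < 2:
            return True
        diffs = np.diff(ll)
        ok = diffs >= -rtol * np.abs(ll[:-1])
        for idx in self.interventions:
            if 1 <= idx < ll.size:
                ok[idx - 1] = True
        return bool(np.all(ok))


# ---------------------------------------------------------------------------
# numerical core
# ---------------------------------------------------------------------------

def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Row-wise log N(x; mean, cov) via Cholesky."""
    D = mean.size
    try:
        L = cholesky(cov, lower=True)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "degenerate covariance (not positive-definite) despite regularization"
        ) from exc
    diff = X - mean
    sol = np.linalg.solve(L, diff.T)
    quad = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (D * np.log(2.0 * np.pi) + logdet + quad)


def _estep(
    X: np.ndarray,
    log_prior: np.ndarray,  # (N, C)
    means: np.ndarray,
    covs: np.ndarray,
    weights: np.ndarray,
    class_of: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Responsibilities over (class, component) pairs and the log-likelihood."""
    K = means.shape[0]
    log_r = np.empty((X.shape[0], K))
    for k in range(K):
        log_r[:, k] = (
            log_prior[:, class_of[k]]
            + np.log(weights[k])
            + _log_gaussian(X, means[k], covs[k])
        )
    norm = logsumexp(log_r, axis=1)
    ll = float(np.sum(norm))
    if not np.isfinite(ll):
        raise RuntimeError("non-finite log-likelihood: degenerate model")
    R = np.exp(log_r - norm[:, None])
    return R, ll


def _poly_basis(shape: tuple[int, int, int], idx: np.ndarray, order: int) -> np.ndarray:
    """Monomials (total degree 1..order) of grid coords scaled to [-1, 1],
    evaluated at flat indices ``idx`` and column-centred over those voxels.

    The constant term is excluded (and columns centred) so the overall
    intensity scale stays in the class means, keeping the bias field
    identifiable.
    """
    ii, jj, kk = np.unravel_index(idx, shape)
    coords = []
    for v, n in zip((ii, jj, kk), shape):
        half = max((n - 1) / 2.0, 1.0)
        coords.append((v - (n - 1) / 2.0) / half)
    cols = []
    for total in range(1, order + 1):
        for px in range(total + 1):
            for py in range(total - px + 1):
                pz = total - px - py
                cols.append(coords[0] ** px * coords[1] ** py * coords[2] ** pz)
    B = np.stack(cols, axis=1)
    return B - B.mean(axis=0, keepdims=True)


def n_poly_terms(order: int) -> int:
    return sum(
        (t + 1) * (t + 2) // 2 for t in range(1, order + 1)
    )


def _weighted_moments(X: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    wsum = w.sum()
    mean = (w[:, None] * X).sum(axis=0) / wsum
    d = X - mean
    cov = (w[:, None] * d).T @ d / wsum
    return mean, cov


def _split_component(
    mean: np.ndarray, cov: np.ndarray, n: int
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Place n means along the first principal axis of ``cov``."""
    vals, vecs = eigh(cov)
    axis = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    offsets = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
    return [mean + o * axis for o in offsets], [cov.copy() for _ in range(n)]


def _reg_matrix(X: np.ndarray, cov_reg: float | None) -> np.ndarray:
    """Diagonal covariance regularizer.

    Per-channel by default (1e-6 x that channel's data variance) so that
    channels of very different magnitude — raw signal vs rates in 1/ms — are
    each floored on their own scale; an absolute floor covers constant
    images.  A scalar ``cov_reg`` overrides with cov_reg * I.
    """
    D = X.shape[1]
    if cov_reg is not None:
        return float(cov_reg) * np.eye(D)
    return np.diag(np.maximum(1e-6 * np.var(X, axis=0), 1e-12))


def _prior_matrix(
    stack: ChannelStack,
    idx: np.ndarray,
    priors: list[Volume] | None,
    stationary: np.ndarray | None,
    n_classes: int,
) -> np.ndarray:
    """(N, C) class-prior matrix at masked voxels, rows summing to 1."""
    if priors is not None:
        P = np.stack([p.data.ravel()[idx] for p in priors], axis=1)
        sums = P.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("spatial priors must sum to 1 per voxel (tol 1e-6)")
        P = P / sums[:, None]
    elif stationary is not None:
        P = np.broadcast_to(stationary, (idx.size, n_classes)).copy()
    else:
        P = np.full((idx.size, n_classes), 1.0 / n_classes)
    return np.clip(P, PRIOR_FLOOR, None)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_model(
    stack: ChannelStack,
    specs: list[ClassSpec] | tuple[ClassSpec, ...] = DEFAULT_CLASS_SPECS,
    priors: list[Volume] | None = None,
    seed: int = 0,
    scale_channels: bool = False,
    cov_reg: float | None = None,
    subsample: int = 20000,
) -> TissueModel:
    """Deterministic starting model.

    With spatial priors, each class starts from its prior-weighted channel
    moments; multi-component classes are split along the first principal
    axis.  Without priors, k-means++ on a fixed-seed voxel subsample assigns
    clusters to classes in roster order after sorting cluster centres by
    first-channel mean.
    """
    specs = list(specs)
    X, idx = stack.samples()
    scaling = None
    if scale_channels:
        center = np.median(X, axis=0)
        scale = 1.4826 * np.median(np.abs(X - center), axis=0)
        scale = np.where(scale <= 0, 1.0, scale)
        X = (X - center) / scale
        scaling = {"center": center.tolist(), "scale": scale.tolist()}
        logger.info("robust per-channel z-scaling active: %s", scaling)
    reg_mat = _reg_matrix(X, cov_reg)
    D = X.shape[1]

    if priors is not None:
        if len(priors) != len(specs):
            raise ValueError("one prior volume per class required")
        for p in priors:
            check_grid(stack.grid, p)
        P = _prior_matrix(stack, idx, priors, None, len(specs))
        components: list[list[GaussianComponent]] = []
        for ci, spec in enumerate(specs):
            mean, cov = _weighted_moments(X, P[:, ci])
            cov = cov + reg_mat
            ms, cs = _split_component(mean, cov, spec.n_components)
            w = 1.0 / spec.n_components
            components.append(
                [GaussianComponent(m, c, w) for m, c in zip(ms, cs)]
            )
        model = TissueModel(
            class_specs=specs,
            components=components,
            channel_names=list(stack.channel_names),
            stationary_priors=None,
            prior_volumes=priors,
            scaling=scaling,
            seed=seed,
        )
        return model

    # prior-free: k-means++ clustering, clusters dealt to classes by
    # first-channel intensity order
    from sklearn.cluster import KMeans

    K_total = sum(s.n_components for s in specs)
    rng = np.random.default_rng(seed)
    if X.shape[0] > subsample:
        pick = rng.choice(X.shape[0], size=subsample, replace=False)
        Xs = X[pick]
    else:
        Xs = X
    n_distinct = np.unique(Xs, axis=0).shape[0]
    if n_distinct < K_total:
        raise ValueError(
            f"{K_total} components requested but only {n_distinct} distinct "
            "voxel values available"
        )
    km = KMeans(
        n_clusters=K_total, init="k-means++", n_init=1,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(Xs)
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
    labels = km.labels_
    counts = np.bincount(labels, minlength=K_total).astype(float)

    components = []
    stat = []
    pos = 0
    for spec in specs:
        comps = []
        cl_ids = order[pos : pos + spec.n_components]
        pos += spec.n_components
        sizes = counts[cl_ids]
        wsum = sizes.sum()
        for cid, sz in zip(cl_ids, sizes):
            sel = Xs[labels == cid]
            mean = sel.mean(axis=0)
            cov = np.cov(sel.T, bias=True).reshape(D, D) + reg_mat
            comps.append(GaussianComponent(mean, cov, float(sz / wsum)))
        stat.append(wsum / counts.sum())
        components.append(comps)

    return TissueModel(
        class_specs=specs,
        components=components,
        channel_names=list(stack.channel_names),
        stationary_priors=np.array(stat),
        prior_volumes=None,
        scaling=scaling,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def em_fit(
    stack: ChannelStack,
    model: TissueModel,
    max_iter: int = 200,
    rel_tol: float = 1e-6,
    cov_reg: float | None = None,
    bias_order: int = 0,
    min_component_voxels: int = 10,
) -> tuple[TissueModel, FitTrace]:
    """Run EM from ``model``; returns the refitted model and its trace.

    ``max_iter = 0`` returns the initial model unchanged with an empty trace.
    """
    if model.n_channels != stack.n_channels:
        raise ValueError(
            f"model has {model.n_channels} channels, stack {stack.n_channels}"
        )
    trace = FitTrace(seed=model.seed)
    if max_iter == 0:
        return model, trace

    X_raw, idx = stack.samples()
    if model.scaling is not None:
        center = np.asarray(model.scaling["center"])
        scale = np.asarray(model.scaling["scale"])
        X_raw = (X_raw - center) / scale
    reg_mat = _reg_matrix(X_raw, cov_reg)
    D = X_raw.shape[1]

    means, covs, weights, class_of = model._flat()
    C = model.n_classes
    stationary = (
        model.stationary_priors.copy()
        if model.stationary_priors is not None else None
    )
    P = _prior_matrix(stack, idx, model.prior_volumes, stationary, C)
    log_prior = np.log(P)

    basis = None
    beta = None
    if bias_order > 0:
        if model.scaling is not None:
            raise ValueError(
                "bias correction operates on raw positive intensities; "
                "disable channel scaling when bias_order > 0"
            )
        basis = _poly_basis(stack.shape, idx, bias_order)
        if (
            model.bias_coefficients is not None
            and model.bias_coefficients.shape == (basis.shape[1], D)
        ):
            beta = model.bias_coefficients.copy()
        else:
            beta = np.zeros((basis.shape[1], D))
    X = X_raw * np.exp(-(basis @ beta)) if beta is not None else X_raw

    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        R, ll = _estep(X, log_prior, means, covs, weights, class_of)
        trace.log_likelihood.append(ll)
        if prev_ll > -np.inf and abs(ll - prev_ll) <= rel_tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll

        # M-step
        Nk = R.sum(axis=0)
        for k in range(len(Nk)):
            if Nk[k] <= 0:
                Nk[k] = PRIOR_FLOOR
            means[k] = (R[:, k][:, None] * X).sum(axis=0) / Nk[k]
            d = X - means[k]
            covs[k] = (R[:, k][:, None] * d).T @ d / Nk[k] + reg_mat
        for ci in range(C):
            sel = class_of == ci
            tot = Nk[sel].sum()
            weights[sel] = Nk[sel] / max(tot, PRIOR_FLOOR)
            if stationary is not None:
                stationary[ci] = tot / X.shape[0]
        if stationary is not None:
            stationary /= stationary.sum()
            log_prior = np.log(
                np.clip(
                    np.broadcast_to(stationary, (X.shape[0], C)),
                    PRIOR_FLOOR, None,
                )
            )

        # degenerate components: re-seed from the heaviest sibling
        for k in range(len(Nk)):
            if Nk[k] < min_component_voxels:
                sib = [
                    j for j in range(len(Nk))
                    if class_of[j] == class_of[k] and j != k
                ]
                if not sib:
                    continue
                j = sib[int(np.argmax(Nk[sib]))]
                logger.info(
                    "component %d starved (%.1f voxels); splitting sibling %d",
                    k, Nk[k], j,
                )
                ms, cs = _split_component(means[j], covs[j], 2)
                means[k], means[j] = ms[0], ms[1]
                covs[k] = cs[0] + reg_mat
                covs[j] = cs[1] + reg_mat
                half = (weights[k] + weights[j]) / 2.0
                weights[k] = weights[j] = max(half, PRIOR_FLOOR)
                trace.interventions.append(len(trace.log_likelihood))

        # bias field update.  Minimising the precision- and responsibility-
        # weighted squared log-residual
        #   sum_{n,k} (r_nk / s_k^2) (log x_n - b(v_n) - log mu_k)^2,
        # s_k^2 = component log-scale variance diag(Sigma_k)/mu_k^2, over b
        # in the basis span is a per-channel weighted least squares with
        # voxel weight W_n = sum_k r_nk/s_k^2 and target
        # log x_n - sum_k (r_nk/s_k^2) log mu_k / W_n.  The weighting keeps
        # low-intensity, high-relative-noise voxels (e.g. attenuated fluid)
        # from polluting the smooth field estimate.
        if beta is not None:
            logmu = np.log(np.clip(means, 1e-12, None))
            ok = np.all(X_raw > 0, axis=1)
            logx = np.where(ok[:, None], np.log(np.where(ok[:, None], X_raw, 1.0)), 0.0)
            for ci in range(D):
                s2 = np.maximum(
                    np.array([covs[k][ci, ci] for k in range(len(means))])
                    / np.clip(means[:, ci] ** 2, 1e-12, None),
                    1e-6,
                )
                Wk = R / s2  # (N, K)
                Wn = Wk.sum(axis=1) * ok
                t = logx[:, ci] - (Wk @ logmu[:, ci]) / np.clip(Wk.sum(axis=1), 1e-300, None)
                bw = basis * Wn[:, None]
                beta[:, ci] = np.linalg.solve(bw.T @ basis, bw.T @ t)
            X = X_raw * np.exp(-(basis @ beta))

    trace.iterations = it
    trace.converged = converged

    # rebuild structured model
    components: list[list[GaussianComponent]] = []
    k = 0
    for spec in model.class_specs:
        comps = []
        for _ in range(spec.n_components):
            comps.append(GaussianComponent(means[k], covs[k], float(weights[k])))
            k += 1
        # renormalise against float drift
        tot = sum(c.weight for c in comps)
        for c in comps:
            c.weight /= tot
        components.append(comps)

    fitted = TissueModel(
        class_specs=list(model.class_specs),
        components=components,
        channel_names=list(model.channel_names),
        stationary_priors=stationary,
        prior_volumes=model.prior_volumes,
        bias_order=bias_order,
        bias_coefficients=beta,
        scaling=model.scaling,
        seed=model.seed,
        config={
            "max_iter": max_iter, "rel_tol": rel_tol,
            "cov_reg": np.diag(reg_mat).tolist(),
            "bias_order": bias_order,
            "min_component_voxels": min_component_voxels,
        },
    )
    return fitted, trace


def posterior_maps(stack: ChannelStack, model: TissueModel) -> TissueProbabilityMaps:
    """Per-voxel class posteriors (components summed within class).

    Outside-mask voxels are 0 in every class map.
    """
    X, idx = stack.samples()
    if model.scaling is not None:
        X = (X - np.asarray(model.scaling["center"])) / np.asarray(
            model.scaling["scale"]
        )
    if model.bias_order > 0 and model.bias_coefficients is not None:
        basis = _poly_basis(stack.shape, idx, model.bias_order)
        X = X * np.exp(-(basis @ model.bias_coefficients))
    means, covs, weights, class_of = model._flat()
    P = _prior_matrix(
        stack, idx, model.prior_volumes, model.stationary_priors, model.n_classes
    )
    R, _ = _estep(X, np.log(P), means, covs, weights, class_of)

    maps = []
    for ci in range(model.n_classes):
        flat = np.zeros(int(np.prod(stack.shape)))
        flat[idx] = R[:, class_of == ci].sum(axis=1)
        maps.append(stack.grid.like(flat.reshape(stack.shape)))
    return TissueProbabilityMaps(maps, model.class_names)


def segment(
    stack: ChannelStack,
    specs: list[ClassSpec] | tuple[ClassSpec, ...] = DEFAULT_CLASS_SPECS,
    priors: list[Volume] | None = None,
    config: dict | None = None,
    seed: int = 0,
) -> tuple[TissueModel, TissueProbabilityMaps, FitTrace]:
    """init_model -> em_fit -> posterior_maps in one call."""
    config = dict(config or {})
    scale_channels = config.pop("scale_channels", False)
    model0 = init_model(
        stack, specs, priors=priors, seed=seed, scale_channels=scale_channels,
        cov_reg=config.get("cov_reg"),
    )
    model, trace = em_fit(stack, model0, **config)
    maps = posterior_maps(stack, model)
    return model, maps, trace


# ---------------------------------------------------------------------------
# model object interface
# ---------------------------------------------------------------------------

class MultichannelMixture:
    """Gaussian-mixture tissue classification model for an N-channel stack.

    Examples
    --------
    >>> model = MultichannelMixture(stack, priors=priors)
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    >>> res.tissue_probability_maps.get("GM")
    """

    def __init__(
        self,
        stack: ChannelStack,
        class_specs: list[ClassSpec] | tuple[ClassSpec, ...] = DEFAULT_CLASS_SPECS,
        priors: list[Volume] | None = None,
        scale_channels: bool = False,
    ) -> None:
        self.stack = stack
        self.class_specs = list(class_specs)
        self.priors = priors
        self.scale_channels = scale_channels

    @classmethod
    def from_volumes(
        cls,
        volumes: list[Volume],
        names: list[str],
        mask: Volume | None = None,
        **kwargs,
    ) -> "MultichannelMixture":
        from .volumes import stack_channels

        return cls(stack_channels(volumes, names, mask), **kwargs)

    def fit(
        self,
        seed: int = 0,
        max_iter: int = 200,
        rel_tol: float = 1e-6,
        cov_reg: float | None = None,
        bias_order: int = 0,
        min_component_voxels: int = 10,
    ) -> "MixtureResults":
        model0 = init_model(
            self.stack, self.class_specs, priors=self.priors, seed=seed,
            scale_channels=self.scale_channels, cov_reg=cov_reg,
        )
        fitted, trace = em_fit(
            self.stack, model0,
            max_iter=max_iter, rel_tol=rel_tol, cov_reg=cov_reg,
            bias_order=bias_order, min_component_voxels=min_component_voxels,
        )
        return MixtureResults(self, fitted, trace)


class MixtureResults:
    """Results of a :class:`MultichannelMixture` fit."""

    def __init__(
        self, model: MultichannelMixture, params: TissueModel, trace: FitTrace
    ) -> None:
        self.model = model
        self.params = params
        self.trace = trace
        self._tpm: TissueProbabilityMaps | None = None

    @property
    def tissue_probability_maps(self) -> TissueProbabilityMaps:
        if self._tpm is None:
            self._tpm = posterior_maps(self.model.stack, self.params)
        return self._tpm

    def separation(self, label: str = "") -> "SeparationReport":  # noqa: F821
        from .separation import class_separation

        return class_separation(self.params, configuration=label)

    def summary(self) -> str:
        import pandas as pd

        rows = []
        for spec, comps in zip(self.params.class_specs, self.params.components):
            for j, c in enumerate(comps, start=1):
                row = {
                    "class": spec.name,
                    "component": j,
                    "weight": round(c.weight, 4),
                }
                for name, mu, var in zip(
                    self.params.channel_names, c.mean, np.diag(c.covariance)
                ):
                    row[f"mean[{name}]"] = round(float(mu), 4)
                    row[f"sd[{name}]"] = round(float(np.sqrt(var)), 4)
                rows.append(row)
        table = pd.DataFrame(rows).to_string(index=False)
        ll = self.trace.log_likelihood[-1] if self.trace.log_likelihood else np.nan
        prior = (
            "spatial volumes" if self.params.prior_volumes is not None
            else "stationary "
            + np.array2string(
                self.params.stationary_priors, precision=3
            )
            if self.params.stationary_priors is not None
            else "uniform"
        )
        head = (
            "Multichannel Gaussian-mixture segmentation\n"
            "==========================================\n"
            f"channels:       {', '.join(self.params.channel_names)}\n"
            f"class priors:   {prior}\n"
            f"log-likelihood: {ll:.4f}\n"
            f"iterations:     {self.trace.iterations} "
            f"(converged: {self.trace.converged})\n"
        )
        return head + table

    def save(self, outdir: str | Path, prefix: str = "seg") -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"model": str(outdir / f"{prefix}_model.json")}
        self.params.to_json(outdir / f"{prefix}_model.json")
        manifest.update(self.tissue_probability_maps.to_files(outdir, prefix))
        return manifest
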