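"""Overlap between fitted tissue-class densities.

The Bhattacharyya distance between two multivariate Gaussians
N(mu1, Sigma1), N(mu2, Sigma2) is (Kailath form)

    DB = 1/8 (mu1-mu2)' Sbar^{-1} (mu1-mu2)
         + 1/2 ln( |Sbar| / sqrt(|Sigma1| |Sigma2|) ),   Sbar = (Sigma1+Sigma2)/2.

It is the negative log of the Bhattacharyya coefficient ∫ sqrt(p q) dx, so it
vanishes exactly for identical densities and grows with class separability.
Computation uses Cholesky factorizations (log-determinants and triangular
solves, never explicit inverses).  Between full tissue classes, the
convention is to take each class's largest-weight mixture component as its
representative; all component-to-component distances are also tabulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky

from .mixture import GaussianComponent, TissueModel


def _chol_logdet_and_quad(cov: np.ndarray, diff: np.ndarray | None = None):
    L = cholesky(cov, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if diff is None:
        return logdet, None
    sol = np.linalg.solve(L, diff)
    return logdet, float(np.dot(sol, sol))


def bhattacharyya(a: GaussianComponent, b: GaussianComponent) -> float:
    """Bhattacharyya distance between two Gaussian components."""
    if a.dim != b.dim:
        raise ValueError(f"dimension mismatch: {a.dim} vs {b.dim}")
    sbar = 0.5 * (a.covariance + b.covariance)
    diff = a.mean - b.mean
    try:
        logdet_bar, quad = _chol_logdet_and_quad(sbar, diff)
        logdet_a, _ = _chol_logdet_and_quad(a.covariance)
        logdet_b, _ = _chol_logdet_and_quad(b.covariance)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariances must be positive-definite") from exc
    return 0.125 * quad + 0.5 * (logdet_bar - 0.5 * (logdet_a + logdet_b))


def hellinger(a: GaussianComponent, b: GaussianComponent) -> float:
    """Hellinger distance sqrt(1 - exp(-DB)); bounded in [0, 1)."""
    return float(np.sqrt(max(0.0, 1.0 - np.exp(-bhattacharyya(a, b)))))


@dataclass
class SeparationReport:
    """Pairwise class/component Bhattacharyya distances for one fit.

    ``table`` lists every component pair (within and across classes);
    ``headline`` maps frozenset class pairs to the distance between the two
    classes' largest-weight components — the convention for quoting, e.g.,
    GM-CSF separation when CSF is a multi-Gaussian mixture.
    """

    table: pd.DataFrame
    headline: dict[tuple[str, str], float]
    configuration: str = ""
    convention: str = "largest-weight component per class"
    scaling: dict | None = None
    extra: dict = field(default_factory=dict)

    def distance(self, class_a: str, class_b: str) -> float:
        key = tuple(sorted((class_a, class_b)))
        return self.headline[key]

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "configuration": self.configuration,
            "convention": self.convention,
            "scaling": self.scaling,
            "headline": [
                {"class_a": k[0], "class_b": k[1], "distance": v}
                for k, v in sorted(self.headline.items())
            ],
            "pairs": self.table.to_dict(orient="records"),
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)
        return path

    @classmethod
    def from_json(cls, source: str | Path) -> "SeparationReport":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            obj = json.loads(Path(source).read_text())
        else:
            obj = json.loads(str(source))
        headline = {
            (h["class_a"], h["class_b"]): h["distance"] for h in obj["headline"]
        }
        return cls(
            table=pd.DataFrame(obj["pairs"]),
            headline=headline,
            configuration=obj.get("configuration", ""),
            convention=obj.get("convention", ""),
            scaling=obj.get("scaling"),
        )


def class_separation(model: TissueModel, configuration: str = "") -> SeparationReport:
    """All pairwise component distances plus largest-weight class headline."""
    rows = []
    names = model.class_names
    labelled = []  # (class, comp_idx, label, component)
    for cname in names:
        comps = model.class_components(cname)
        for j, comp in enumerate(comps, start=1):
            label = cname if len(comps) == 1 else f"{cname}{j}"
            labelled.append((cname, j, label, comp))
    for i in range(len(labelled)):
        for j in range(i + 1, len(labelled)):
            ca, _, la, compa = labelled[i]
            cb, _, lb, compb = labelled[j]
            rows.append(
                {
                    "class_a": ca, "component_a": la,
                    "weight_a": round(compa.weight, 6),
                    "class_b": cb, "component_b": lb,
                    "weight_b": round(compb.weight, 6),
                    "distance": bhattacharyya(compa, compb),
                }
            )
    headline = {}
    for i, ca in enumerate(names):
        for cb in names[i + 1 :]:
            headline[tuple(sorted((ca, cb)))] = bhattacharyya(
                model.representative(ca), model.representative(cb)
            )
    return SeparationReport(
        table=pd.DataFrame(rows),
        headline=headline,
        configuration=configuration,
        scaling=model.scaling,
    )


@dataclass
class PairedSeparationTest:
    mean_difference: float
    t_statistic: float
    p_value: float
    n: int
    zero_variance: bool = False


def paired_separation_test(
    reports_a: list[SeparationReport],
    reports_b: list[SeparationReport],
    pair: tuple[str, str] = ("GM", "CSF"),
) -> PairedSeparationTest:
    """Two-sided paired t-test on a class-pair distance across matched fits.

    Differences are taken b - a (e.g. multimodal minus unimodal), matched by
    list position (subject/replicate order).
    """
    if len(reports_a) != len(reports_b):
        raise ValueError("report lists must have equal length")
    n = len(reports_a)
    if n < 2:
        raise ValueError("paired test needs at least 2 matched fits")
    da = np.array([r.distance(*pair) for r in reports_a])
    db = np.array([r.distance(*pair) for r in reports_b])
    diffs = db - da
    if np.allclose(diffs.std(ddof=1), 0.0):
        # all differences identical; t undefined unless they are all 0
        mean = float(diffs.mean())
        return PairedSeparationTest(
            mean_difference=mean,
            t_statistic=0.0 if mean == 0 else np.inf * np.sign(mean),
            p_value=1.0 if mean == 0 else 0.0,
            n=n,
            zero_variance=True,
        )
    t, p = stats.ttest_rel(db, da)
    return PairedSeparationTest(
        mean_difference=float(diffs.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n=n,
    )
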