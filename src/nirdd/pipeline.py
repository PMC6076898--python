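"""The authentication experiment: SNV -> PCA -> Kennard-Stone split -> one-class
models -> sensitivity/specificity report, plus the kernel-width boundary study.

Protocol
--------
For each brand in turn the brand's samples are the *target class* and all
other samples are *outliers*.  Features are either the first two principal
component scores of the SNV-preprocessed spectra (``pc2``, the default; PCA
fitted once on all samples jointly) or the SNV spectra themselves
(``original``).  The target samples are ranked by the Kennard-Stone maximin
criterion and the first ``n_train`` (default 30) most representative form the
training set; the remaining target samples plus every other-class sample form
the test set.  SVDD, KNNDD and the Gaussian description are fitted on the
training set only and evaluated on the test set:

* sensitivity = % of target test samples accepted,
* specificity = % of outlier test samples rejected.

Metrics are computed in full precision and rounded half-up to one decimal
only for reporting; the Average row is the mean of the unrounded class rows.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .chemometrics import PCAModel, kennard_stone_rank, pca_fit
from .data_description import (
    GaussianDDResults,
    KernelSpec,
    KNNDDResults,
    SVDDResults,
    boundary_grid,
    gauss_fit,
    knndd_fit,
    svdd_fit,
)
from .spectra import SpectraSet, snv_transform
from .synthetic import simulate_study

__all__ = [
    "StudyConfig",
    "SplitPlan",
    "EvalReport",
    "TargetRun",
    "WidthScanResult",
    "AuthenticationStudy",
    "StudyResults",
    "make_split",
    "evaluate",
    "width_scan",
    "default_sigma_grid",
    "run_study",
    "round_half_up",
]

METHODS = ("GAUSS", "KNNDD", "SVDD")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class StudyConfig:
    """All tunable knobs of the experiment, with the study defaults."""

    feature_space: str = "pc2"  # "pc2" | "original"
    n_components: int = 2
    n_train: int = 30
    rejection_fraction: float = 0.1
    sigma: float | str = "auto"  # RBF width, or "auto" for the width-scan heuristic
    sigma_grid: tuple[float, ...] | None = None
    k: int = 1
    knn_threshold: float = 1.0
    gauss_coverage: float = 0.95
    gauss_lambda: float | None = None
    gauss_inv_mode: str = "regularized"
    strict_pca: bool = False  # fit PCA on the training rows only

    def __post_init__(self) -> None:
        if self.feature_space not in ("pc2", "original"):
            raise ValueError(f"unknown feature_space {self.feature_space!r}")
        if isinstance(self.sigma, str) and self.sigma != "auto":
            raise ValueError("sigma must be a positive number or 'auto'")


@dataclass
class SplitPlan:
    """Train/test partition for one target class."""

    target_class: str
    n_train: int
    train_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError("train and test sets overlap")


def make_split(
    spectra: SpectraSet,
    X: np.ndarray,
    target_class: str,
    n_train: int = 30,
) -> SplitPlan:
    """Kennard-Stone split of the target class in feature space ``X``.

    ``X`` must be row-aligned with ``spectra``.  The target samples are
    ranked by :func:`kennard_stone_rank` on their feature rows; the first
    ``n_train`` become the training set, the remaining target samples plus
    all other-class samples the test set (original row order).
    """
    labels = spectra.labels
    target_idx = np.flatnonzero(labels == target_class)
    if target_idx.size == 0:
        raise ValueError(f"no samples with label {target_class!r}")
    if n_train >= target_idx.size:
        raise ValueError(
            f"n_train={n_train} must be smaller than the target class size "
            f"{target_idx.size}"
        )
    ranking = kennard_stone_rank(np.asarray(X)[target_idx])
    train = target_idx[ranking.head(n_train)]
    rest_target = target_idx[ranking.order[n_train:]]
    others = np.flatnonzero(labels != target_class)
    test = np.sort(np.concatenate([rest_target, others]))
    return SplitPlan(
        target_class=target_class,
        n_train=n_train,
        train_indices=train,
        test_indices=test,
    )


def evaluate(
    accepted: np.ndarray, test_labels: np.ndarray, target_class: str
) -> tuple[float, float]:
    """Unrounded (sensitivity, specificity) in percent for one test set."""
    accepted = np.asarray(accepted, dtype=bool)
    test_labels = np.asarray(test_labels)
    if accepted.size != test_labels.size:
        raise ValueError("one prediction per test sample required")
    is_target = test_labels == target_class
    n_t = int(is_target.sum())
    n_o = int((~is_target).sum())
    if n_t == 0 or n_o == 0:
        raise ValueError(
            "sensitivity/specificity undefined: test set needs both target "
            f"and outlier samples (got {n_t} targets, {n_o} outliers)"
        )
    sensitivity = 100.0 * accepted[is_target].sum() / n_t
    specificity = 100.0 * (~accepted[~is_target]).sum() / n_o
    return float(sensitivity), float(specificity)


class EvalReport:
    """Per-class and average sensitivity/specificity table (percent).

    Values are stored unrounded; :meth:`to_dataframe` and :meth:`summary`
    round half-up to one decimal, with the Average row computed from the
    unrounded class values.
    """

    def __init__(self) -> None:
        # rows[target][method] = (sensitivity, specificity), unrounded
        self.rows: dict[str, dict[str, tuple[float, float]]] = {}

    def add(self, target: str, method: str, sensitivity: float, specificity: float):
        self.rows.setdefault(target, {})[method] = (float(sensitivity), float(specificity))

    def methods(self) -> list[str]:
        ms = [m for m in METHODS if any(m in r for r in self.rows.values())]
        extra = sorted(
            {m for r in self.rows.values() for m in r} - set(ms)
        )
        return ms + extra

    def average(self, method: str) -> tuple[float, float]:
        vals = [self.rows[t][method] for t in self.rows if method in self.rows[t]]
        sen = float(np.mean([v[0] for v in vals]))
        spe = float(np.mean([v[1] for v in vals]))
        return sen, spe

    def to_dataframe(self) -> pd.DataFrame:
        methods = self.methods()
        records = []
        for target in self.rows:
            rec: dict[str, float | str] = {"target": target}
            for m in methods:
                sen, spe = self.rows[target][m]
                rec[f"{m}_SPE"] = round_half_up(spe)
                rec[f"{m}_SEN"] = round_half_up(sen)
            records.append(rec)
        if len(self.rows) > 1:
            rec = {"target": "Average"}
            for m in methods:
                sen, spe = self.average(m)
                rec[f"{m}_SPE"] = round_half_up(spe)
                rec[f"{m}_SEN"] = round_half_up(sen)
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def summary(self) -> str:
        df = self.to_dataframe()
        lines = ["Authentication performance (SPE/SEN, %)", "=" * 55]
        lines.append(df.to_string(index=False))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class TargetRun:
    """Everything produced for one target class."""

    target_class: str
    split: SplitPlan
    features: np.ndarray
    pca: PCAModel | None
    sigma: float
    width_scan: "WidthScanResult | None"
    models: dict[str, object] = field(default_factory=dict)
    predictions: dict[str, np.ndarray] = field(default_factory=dict)
    metrics: dict[str, tuple[float, float]] = field(default_factory=dict)


def default_sigma_grid(X: np.ndarray, n: int = 25) -> np.ndarray:
    """Log-spaced RBF-width grid from the mean NN distance to the diameter.

    These two scales bracket the qualitative regimes of the RBF width:
    below the mean nearest-neighbour distance the description degenerates
    toward Parzen windows around individual points, above the data diameter
    toward the rigid hypersphere.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    tree = cKDTree(X)
    d, _ = tree.query(X, k=2)
    nn_mean = float(np.mean(d[:, 1]))
    sq = np.sum(X**2, axis=1)
    diam = float(
        np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0)).max()
    )
    lo = max(nn_mean, 1e-8)
    hi = max(diam, 10 * lo)
    return np.geomspace(lo, hi, n)


@dataclass
class WidthScanResult:
    """Per-sigma SVDD summaries of a kernel-width scan, ordered by sigma."""

    sigmas: np.ndarray
    results: list[SVDDResults]
    rejection_fraction: float
    boundary_grids: list[pd.DataFrame] | None = None

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for s, r in zip(self.sigmas, self.results):
            rows.append(
                {
                    "sigma": s,
                    "n_support": r.n_support,
                    "n_bounded": r.n_bounded,
                    "n_train_rejected": int(
                        (r.dist2_train > r.radius2 + r.boundary_tol).sum()
                    ),
                    "radius2": r.radius2,
                    "all_training_accepted": bool(
                        (r.dist2_train <= r.radius2 + r.boundary_tol).all()
                    ),
                }
            )
        return pd.DataFrame(rows)

    def select_sigma(self) -> float:
        """Tightest *simple* boundary containing all training samples.

        Among the scanned widths whose description accepts every training
        sample, return the one with the fewest support vectors — the support
        vector count measures boundary complexity, falling from the
        Parzen-window regime (every point a support vector, a wiggly union
        of bubbles) to the rigid-hypersphere regime — breaking ties toward
        the smallest sigma (the tightest of the simple boundaries).  If no
        scanned width accepts all training samples, minimize rejections
        first, then proceed the same way.
        """
        t = self.table
        ok = t[t["all_training_accepted"]]
        if not len(ok):
            ok = t[t["n_train_rejected"] == t["n_train_rejected"].min()]
        simplest = ok[ok["n_support"] == ok["n_support"].min()]
        return float(simplest["sigma"].iloc[0])


def width_scan(
    X: np.ndarray,
    sigmas,
    rejection_fraction: float = 0.1,
    bbox: tuple[float, float, float, float] | None = None,
    grid_n: int = 60,
) -> WidthScanResult:
    """Fit an SVDD per RBF width and summarize the boundary behaviour.

    ``sigmas`` need not be sorted; results are ordered by sigma.  When a
    2-D ``bbox`` is given, a boundary score grid is attached per width.
    """
    sigmas = np.asarray(list(sigmas), dtype=float)
    if sigmas.size < 1:
        raise ValueError("at least one sigma required")
    if np.any(sigmas <= 0):
        raise ValueError("all sigmas must be positive")
    sigmas = np.sort(sigmas)
    results, grids = [], []
    for s in sigmas:
        r = svdd_fit(X, KernelSpec("rbf", float(s)), rejection_fraction)
        results.append(r)
        if bbox is not None:
            grids.append(boundary_grid(r, bbox, n=grid_n))
    return WidthScanResult(
        sigmas=sigmas,
        results=results,
        rejection_fraction=rejection_fraction,
        boundary_grids=grids if bbox is not None else None,
    )


class AuthenticationStudy:
    """The full experiment as a fittable model object.

    Parameters
    ----------
    spectra : SpectraSet
        Labelled absorbance spectra (raw; SNV is applied internally).
    config : StudyConfig, optional
        Experiment knobs; defaults reproduce the study protocol.
    """

    def __init__(self, spectra: SpectraSet, config: StudyConfig | None = None) -> None:
        self.spectra = spectra
        self.config = config if config is not None else StudyConfig()

    # -- feature extraction -------------------------------------------------
    def _features_joint(self) -> tuple[np.ndarray, PCAModel | None]:
        snv = snv_transform(self.spectra)
        if self.config.feature_space == "original":
            return snv.absorbance, None
        pca = pca_fit(snv.absorbance, self.config.n_components)
        return pca.transform(snv.absorbance), pca

    def run_target(self, target_class: str) -> TargetRun:
        """Fit and evaluate the three descriptions for one target class."""
        cfg = self.config
        snv = snv_transform(self.spectra)
        if cfg.feature_space == "pc2" and cfg.strict_pca:
            # strict mode: rank in SNV space, fit PCA on the training rows only
            split = make_split(self.spectra, snv.absorbance, target_class, cfg.n_train)
            pca = pca_fit(snv.absorbance[split.train_indices], cfg.n_components)
            features = pca.transform(snv.absorbance)
        else:
            features, pca = self._features_joint()
            split = make_split(self.spectra, features, target_class, cfg.n_train)
        Xtr = features[split.train_indices]
        Xte = features[split.test_indices]
        test_labels = self.spectra.labels[split.test_indices]

        scan = None
        if isinstance(cfg.sigma, str):  # "auto"
            grid = (
                np.asarray(cfg.sigma_grid, dtype=float)
                if cfg.sigma_grid is not None
                else default_sigma_grid(Xtr)
            )
            scan = width_scan(Xtr, grid, cfg.rejection_fraction)
            sigma = scan.select_sigma()
        else:
            sigma = float(cfg.sigma)

        run = TargetRun(
            target_class=target_class,
            split=split,
            features=features,
            pca=pca,
            sigma=sigma,
            width_scan=scan,
        )
        fitters = {
            "SVDD": lambda: svdd_fit(
                Xtr, KernelSpec("rbf", sigma), cfg.rejection_fraction
            ),
            "KNNDD": lambda: knndd_fit(Xtr, cfg.k, cfg.knn_threshold),
            "GAUSS": lambda: gauss_fit(
                Xtr, cfg.gauss_lambda, cfg.gauss_coverage, cfg.gauss_inv_mode
            ),
        }
        for name, fitter in fitters.items():
            try:
                model = fitter()
                accepted = model.predict(Xte)
            except Exception as exc:
                raise RuntimeError(
                    f"{name} failed for target class {target_class!r}: {exc}"
                ) from exc
            run.models[name] = model
            run.predictions[name] = accepted
            run.metrics[name] = evaluate(accepted, test_labels, target_class)
        return run

    def fit(self, targets: list[str] | None = None) -> "StudyResults":
        """Run the experiment for each target class and assemble the report."""
        t0 = time.perf_counter()
        targets = targets if targets is not None else self.spectra.classes()
        runs: dict[str, TargetRun] = {}
        report = EvalReport()
        timings: dict[str, float] = {}
        for target in targets:
            ts = time.perf_counter()
            run = self.run_target(target)
            runs[target] = run
            for method, (sen, spe) in run.metrics.items():
                report.add(target, method, sen, spe)
            timings[target] = time.perf_counter() - ts
        timings["total"] = time.perf_counter() - t0
        return StudyResults(study=self, runs=runs, report=report, timings=timings)


@dataclass
class StudyResults:
    """Fitted study: per-target runs and the aggregated report."""

    study: AuthenticationStudy
    runs: dict[str, TargetRun]
    report: EvalReport
    timings: dict[str, float]

    def summary(self) -> str:
        cfg = self.study.config
        lines = [self.report.summary(), ""]
        for target, run in self.runs.items():
            lines.append(
                f"target {target}: n_train={run.split.n_train}, "
                f"n_test={run.split.test_indices.size}, "
                f"sigma={run.sigma:.4g} "
                f"({'auto' if isinstance(cfg.sigma, str) else 'fixed'})"
            )
        return "\n".join(lines)

    def save(self, outdir) -> Path:
        """Write report CSV, model files, boundary grids and a run log."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(out / "report.csv")
        cfg = self.study.config
        log = [
            "authentication study run log",
            f"config: {json.dumps(asdict(cfg), default=str)}",
        ]
        for target, run in self.runs.items():
            for method, model in run.models.items():
                with open(out / f"model_{target}_{method}.json", "w") as fh:
                    json.dump(model.to_dict(), fh, indent=1)
            if run.features.shape[1] == 2:
                Xtr = run.features[run.split.train_indices]
                pad_x = 0.5 * (np.ptp(Xtr[:, 0]) + 1e-9)
                pad_y = 0.5 * (np.ptp(Xtr[:, 1]) + 1e-9)
                bbox = (
                    Xtr[:, 0].min() - pad_x,
                    Xtr[:, 0].max() + pad_x,
                    Xtr[:, 1].min() - pad_y,
                    Xtr[:, 1].max() + pad_y,
                )
                for method, model in run.models.items():
                    boundary_grid(
                        model, bbox, n=60, path=out / f"boundary_{target}_{method}.csv"
                    )
            log.append(
                f"target {target}: sigma={run.sigma!r}, "
                f"train={run.split.train_indices.tolist()}"
            )
            log.append(f"target {target}: elapsed {self.timings[target]:.3f}s")
        log.append(f"total elapsed {self.timings['total']:.3f}s")
        (out / "run.log").write_text("\n".join(log) + "\n")
        return out


def run_study(
    spectra: SpectraSet | None = None,
    config: StudyConfig | None = None,
    simulate_seed: int | None = None,
    outdir=None,
) -> StudyResults:
    """One-call experiment: optionally simulate the study data, fit, save.

    Provide either ``spectra`` or ``simulate_seed`` (which generates the
    default 142-sample synthetic study).
    """
    if spectra is None:
        if simulate_seed is None:
            raise ValueError("provide spectra or simulate_seed")
        spectra = simulate_study(seed=simulate_seed)
    results = AuthenticationStudy(spectra, config).fit()
    if outdir is not None:
        results.save(outdir)
    return results
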