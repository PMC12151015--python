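"""Evaluation protocols for ΔΔG_bind prediction.

Implements the full protocol suite: random 80/20 splits within a complex
or across the whole dataset, leave-one-complex-out and cross-complex
transfer, repeated runs with published seeds, learning curves with a
frozen test half, the experimental-noise correlation ceiling, and
residue-class enrichment among regression outliers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MutationRecord
from .model import BoostParams, DdgBoostModel

logger = logging.getLogger(__name__)

SPLIT_MODES = ("random_within", "leave_one_pdb_out", "cross_pdb", "learning_curve")

#: Published repeat seeds so "repeated three/five times" is reproducible.
DEFAULT_REPEAT_SEEDS = (101, 102, 103, 104, 105)

#: Residue classes used in the outlier analysis (mutant residue letter).
RESIDUE_CLASSES: Mapping[str, frozenset] = {
    "hydrophobic": frozenset("FILYMV"),
    "polar": frozenset("DEKNQR"),
    "structure_disrupting": frozenset("PGN"),
}


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rmse(pred: Sequence[float], exp: Sequence[float]) -> float:
    """Root mean square error sqrt((1/n) Σ (Yi − Ŷi)²), in kcal/mol."""
    pred = np.asarray(pred, dtype=np.float64)
    exp = np.asarray(exp, dtype=np.float64)
    if pred.shape != exp.shape or pred.ndim != 1 or pred.size < 1:
        raise ValueError(f"need equal-length 1-D vectors, got {pred.shape} and {exp.shape}")
    return float(np.sqrt(np.mean((exp - pred) ** 2)))


def _check_corr_input(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"need equal-length 1-D vectors, got {a.shape} and {b.shape}")
    if a.size < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")


def pearson(pred: Sequence[float], exp: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    a = np.asarray(pred, dtype=np.float64)
    b = np.asarray(exp, dtype=np.float64)
    _check_corr_input(a, b)
    return float(stats.pearsonr(a, b).statistic)


def spearman(pred: Sequence[float], exp: Sequence[float]) -> float:
    """Rank correlation coefficient."""
    a = np.asarray(pred, dtype=np.float64)
    b = np.asarray(exp, dtype=np.float64)
    _check_corr_input(a, b)
    return float(stats.spearmanr(a, b).statistic)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/test record indices plus how they were made."""

    mode: str
    train_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in SPLIT_MODES:
            raise ValueError(f"mode must be one of {SPLIT_MODES}, got {self.mode!r}")
        train, test = set(self.train_ids), set(self.test_ids)
        if train & test:
            raise ValueError("train and test overlap")
        if not test:
            raise ValueError("test set is empty")


def random_within_split(
    records: Sequence[MutationRecord], train_fraction: float = 0.8, seed: int = 0
) -> SplitSpec:
    """Uniform random partition; |test| = round((1 − train_fraction)·n)."""
    n = len(records)
    if n < 5:
        raise ValueError(f"need at least 5 records to split, got {n}")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_test = int(round((1.0 - train_fraction) * n))
    n_test = min(max(n_test, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return SplitSpec(
        mode="random_within",
        train_ids=tuple(int(i) for i in perm[n_test:]),
        test_ids=tuple(int(i) for i in perm[:n_test]),
        seed=seed,
        params={"train_fraction": train_fraction},
    )


def leave_one_pdb_out_split(
    records: Sequence[MutationRecord], held_out: str
) -> SplitSpec:
    """All records of one complex form the test set; everything else trains."""
    held_out = held_out.upper()
    test = [i for i, r in enumerate(records) if r.pdb_id == held_out]
    train = [i for i, r in enumerate(records) if r.pdb_id != held_out]
    if not test:
        raise ValueError(f"no records for held-out complex {held_out}")
    spec = SplitSpec(
        mode="leave_one_pdb_out",
        train_ids=tuple(train),
        test_ids=tuple(test),
        params={"held_out_pdb": held_out},
    )
    # leakage asserted on every call, not assumed
    train_pdbs = {records[i].pdb_id for i in spec.train_ids}
    test_pdbs = {records[i].pdb_id for i in spec.test_ids}
    assert not train_pdbs & test_pdbs, "complex leaked between train and test"
    return spec


def cross_pdb_split(
    records: Sequence[MutationRecord], source_pdb: str, target_pdb: str
) -> SplitSpec:
    """Train on one complex, test on another."""
    source_pdb, target_pdb = source_pdb.upper(), target_pdb.upper()
    if source_pdb == target_pdb:
        raise ValueError("source and target complexes must differ")
    train = [i for i, r in enumerate(records) if r.pdb_id == source_pdb]
    test = [i for i, r in enumerate(records) if r.pdb_id == target_pdb]
    if not train:
        raise ValueError(f"no records for source complex {source_pdb}")
    if not test:
        raise ValueError(f"no records for target complex {target_pdb}")
    return SplitSpec(
        mode="cross_pdb",
        train_ids=tuple(train),
        test_ids=tuple(test),
        params={"source_pdb": source_pdb, "target_pdb": target_pdb},
    )


# ---------------------------------------------------------------------------
# protocol runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatResult:
    seed: int
    pearson: float
    spearman: float
    rmse: float


@dataclass
class EvalReport:
    """Per-protocol metrics with per-repeat values and their spread."""

    mode: str
    pearson_r: float
    spearman_r: float
    rmse: float
    n_test: int
    per_repeat: list[RepeatResult]
    mean_r: float
    sd_r: float
    params: dict = field(default_factory=dict)
    scatter: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            f"Evaluation protocol: {self.mode}",
            "=" * 44,
            f"{'Repeats:':<26}{len(self.per_repeat)}",
            f"{'Test size:':<26}{self.n_test}",
            f"{'Pearson r (mean ± SD):':<26}{self.mean_r:.3f} ± {self.sd_r:.3f}",
            f"{'Spearman ρ (mean):':<26}{self.spearman_r:.3f}",
            f"{'RMSE (kcal/mol, mean):':<26}{self.rmse:.3f}",
            "=" * 44,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "pearson_r": self.pearson_r,
            "spearman_r": self.spearman_r,
            "rmse": self.rmse,
            "n_test": self.n_test,
            "mean_r": self.mean_r,
            "sd_r": self.sd_r,
            "params": self.params,
            "per_repeat": [
                {"seed": r.seed, "pearson": r.pearson, "spearman": r.spearman, "rmse": r.rmse}
                for r in self.per_repeat
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _default_repeats(records: Sequence[MutationRecord], mode: str) -> int:
    if mode != "random_within":
        return 3
    # three repeats for a single-complex protocol, five for the whole dataset
    return 5 if len({r.pdb_id for r in records}) > 1 else 3


def run_protocol(
    records: Sequence[MutationRecord],
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    mode: str = "random_within",
    repeats: int | None = None,
    seeds: Sequence[int] | None = None,
    params: BoostParams | None = None,
    train_fraction: float = 0.8,
    held_out: str | None = None,
    source_pdb: str | None = None,
    target_pdb: str | None = None,
) -> EvalReport:
    """Train, predict and score once per repeat; report mean and SD of r.

    Each repeat resamples both the random split (where the mode has one) and
    the learner seed.  The scatter table of the last repeat (experimental,
    predicted, residual per test record) is attached for external plotting.
    """
    X = np.asarray(X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.shape[0] != len(records) or y.shape[0] != len(records):
        raise ValueError("features/targets are not aligned with records")
    if repeats is None:
        repeats = len(seeds) if seeds is not None else _default_repeats(records, mode)
    if seeds is None:
        seeds = DEFAULT_REPEAT_SEEDS[:repeats]
    if len(seeds) < repeats:
        raise ValueError(f"{repeats} repeats requested but only {len(seeds)} seeds given")
    seeds = list(seeds)[:repeats]

    per_repeat: list[RepeatResult] = []
    scatter = None
    split_params: dict = {}
    for k, seed in enumerate(seeds):
        try:
            if mode == "random_within":
                split = random_within_split(records, train_fraction, seed=seed)
            elif mode == "leave_one_pdb_out":
                if held_out is None:
                    raise ValueError("leave_one_pdb_out needs held_out")
                split = leave_one_pdb_out_split(records, held_out)
            elif mode == "cross_pdb":
                if source_pdb is None or target_pdb is None:
                    raise ValueError("cross_pdb needs source_pdb and target_pdb")
                split = cross_pdb_split(records, source_pdb, target_pdb)
            else:
                raise ValueError(f"unsupported protocol mode {mode!r}")
            split_params = split.params
            tr, te = list(split.train_ids), list(split.test_ids)
            results = DdgBoostModel(X[tr], y[tr], params=params).fit(seed=seed)
            pred = results.predict(X[te])
            per_repeat.append(RepeatResult(
                seed=seed,
                pearson=pearson(pred, y[te]),
                spearman=spearman(pred, y[te]),
                rmse=rmse(pred, y[te]),
            ))
            scatter = pd.DataFrame({
                "record_index": te,
                "exp": y[te],
                "pred": pred,
                "residual": pred - y[te],
            })
        except Exception as exc:
            raise RuntimeError(f"repeat {k} (seed {seed}) failed: {exc}") from exc

    r_values = np.array([r.pearson for r in per_repeat])
    return EvalReport(
        mode=mode,
        pearson_r=float(r_values.mean()),
        spearman_r=float(np.mean([r.spearman for r in per_repeat])),
        rmse=float(np.mean([r.rmse for r in per_repeat])),
        n_test=len(scatter),
        per_repeat=per_repeat,
        mean_r=float(r_values.mean()),
        sd_r=float(r_values.std(ddof=1)) if len(r_values) > 1 else 0.0,
        params={"train_fraction": train_fraction, **split_params,
                "seeds": list(seeds)},
        scatter=scatter,
    )


# ---------------------------------------------------------------------------
# learning curve
# ---------------------------------------------------------------------------

MIN_CURVE_TRAIN = 10


def learning_curve(
    records: Sequence[MutationRecord],
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    fraction_step: float = 0.05,
    max_fraction: float = 0.5,
    seed: int = 0,
    params: BoostParams | None = None,
) -> list[tuple[float, EvalReport]]:
    """Correlation versus training-set size with a frozen test half.

    Records are split once into two equal halves; the test half never
    changes.  Training subsets are drawn from the other half, grow in
    ``fraction_step`` increments of the full dataset up to ``max_fraction``,
    and are nested (each extends the previous).
    """
    X = np.asarray(X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(records)
    if not 0 < fraction_step <= max_fraction <= 0.5:
        raise ValueError("need 0 < fraction_step <= max_fraction <= 0.5")
    perm = np.random.default_rng(seed).permutation(n)
    test_ids = perm[: n // 2]
    pool = perm[n // 2:]

    n_points = int(round(max_fraction / fraction_step))
    fractions = [(i + 1) * fraction_step for i in range(n_points)]
    if int(round(fractions[0] * n)) < MIN_CURVE_TRAIN:
        raise ValueError(
            f"smallest fraction {fractions[0]} gives fewer than "
            f"{MIN_CURVE_TRAIN} training records"
        )
    points: list[tuple[float, EvalReport]] = []
    for frac in fractions:
        k = min(int(round(frac * n)), len(pool))
        train_ids = pool[:k]  # nested by construction
        results = DdgBoostModel(X[train_ids], y[train_ids], params=params).fit(seed=seed)
        pred = results.predict(X[test_ids])
        rep = RepeatResult(
            seed=seed,
            pearson=pearson(pred, y[test_ids]),
            spearman=spearman(pred, y[test_ids]),
            rmse=rmse(pred, y[test_ids]),
        )
        report = EvalReport(
            mode="learning_curve",
            pearson_r=rep.pearson,
            spearman_r=rep.spearman,
            rmse=rep.rmse,
            n_test=len(test_ids),
            per_repeat=[rep],
            mean_r=rep.pearson,
            sd_r=0.0,
            params={
                "train_fraction": frac,
                "n_train": int(k),
                "test_ids": [int(i) for i in test_ids],
                "train_ids": [int(i) for i in train_ids],
            },
        )
        points.append((frac, report))
    return points


# ---------------------------------------------------------------------------
# noise ceiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseCeilingResult:
    """Distribution of correlations between noisy replicates and the original."""

    r_values: np.ndarray
    mean_r: float
    sd_r: float


def noise_ceiling(
    values: Sequence[float],
    errors: Sequence[float] | float,
    n_sim: int = 1000,
    seed: int = 0,
) -> NoiseCeilingResult:
    """Maximum achievable correlation given per-measurement experimental error.

    Each simulation adds independent Gaussian noise (mean 0, per-point SD
    taken from ``errors``) to the measured values and records the Pearson
    correlation between the noisy replicate and the original.
    """
    values = np.asarray(values, dtype=np.float64)
    errors = np.broadcast_to(np.asarray(errors, dtype=np.float64), values.shape)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("need a 1-D vector of at least 3 measurements")
    if (errors < 0).any():
        raise ValueError("measurement errors must be non-negative")
    if np.ptp(values) == 0:
        raise ValueError("zero-variance measurements have no defined ceiling")
    rng = np.random.default_rng(seed)
    r_values = np.empty(n_sim)
    for i in range(n_sim):
        noisy = values + rng.normal(0.0, errors)
        if np.ptp(noisy) == 0:  # pathological; only possible with zero errors handled below
            r_values[i] = 1.0
        else:
            r_values[i] = pearson(noisy, values)
    return NoiseCeilingResult(
        r_values=r_values,
        mean_r=float(r_values.mean()),
        sd_r=float(r_values.std(ddof=1)) if n_sim > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# outlier enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassTest:
    direction: str
    residue_class: str
    observed_k: int
    n: int
    background_p: float
    p_value: float
    status: str  # "enriched" | "depleted"
    p_adjusted: float | None = None


@dataclass
class EnrichmentReport:
    """Outliers of the prediction-vs-experiment fit and their residue classes.

    Convention: the regression line is predicted-on-experimental; residual =
    predicted − line.  With the destabilizing-positive sign convention for
    ΔΔG_bind, a positive residual means the mutation was predicted to be more
    destabilizing than observed.
    """

    outlier_indices: np.ndarray
    directions: list[str]
    class_tests: list[ClassTest]
    slope: float
    intercept: float
    residual_sd: float
    threshold_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.class_tests])

    def summary(self) -> str:
        lines = [
            "Residual-outlier residue-class enrichment",
            "=" * 52,
            f"{'Outliers (> %.1f σ):' % self.threshold_sd:<30}{len(self.outlier_indices)}",
            f"{'Fit: pred = a·exp + b':<30}a={self.slope:.3f}, b={self.intercept:.3f}",
            f"{'Residual SD (kcal/mol):':<30}{self.residual_sd:.3f}",
        ]
        for t in self.class_tests:
            lines.append(
                f"  {t.direction:<20}{t.residue_class:<22}"
                f"k={t.observed_k}/{t.n}  p0={t.background_p:.3f}  "
                f"P={t.p_value:.3g} ({t.status})"
            )
        lines.append("=" * 52)
        return "\n".join(lines)


def binomial_tail(k: int, n: int, p: float, status: str) -> float:
    """Exact one-sided binomial tail: P(X ≥ k) if enriched, P(X ≤ k) if depleted."""
    if status == "enriched":
        return float(stats.binom.sf(k - 1, n, p))
    return float(stats.binom.cdf(k, n, p))


def _record_mut_letters(record: MutationRecord) -> list[str]:
    return [m.mut_aa for m in record.mutations]


def outlier_enrichment(
    pred: Sequence[float],
    exp: Sequence[float],
    records: Sequence[MutationRecord],
    threshold_sd: float = 1.0,
    classes: Mapping[str, frozenset] | None = None,
    holm: bool = False,
) -> EnrichmentReport:
    """Find fit outliers and test residue classes for enrichment among them.

    An ordinary least-squares line of predicted on experimental values is
    fitted; records whose residual exceeds ``threshold_sd`` residual standard
    deviations are outliers, signed into over-destabilizing (above the line)
    and over-stabilizing (below).  For each direction and residue class an
    exact binomial tail p-value is computed against the class frequency among
    all evaluated mutations (the dataset composition is the null).  P-values
    are reported raw; ``holm=True`` adds a Holm-adjusted column.
    """
    pred = np.asarray(pred, dtype=np.float64)
    exp = np.asarray(exp, dtype=np.float64)
    if pred.shape != exp.shape or len(records) != pred.size:
        raise ValueError("pred, exp and records must be aligned")
    if pred.size < 10:
        raise ValueError("outlier analysis needs at least 10 points")
    if np.ptp(exp) == 0:
        raise ValueError("degenerate regression: experimental values have zero variance")
    classes = dict(classes) if classes is not None else dict(RESIDUE_CLASSES)

    slope, intercept = np.polyfit(exp, pred, 1)
    residual = pred - (slope * exp + intercept)
    sd = float(residual.std(ddof=0))
    if sd == 0:
        raise ValueError("degenerate regression: zero residual variance")

    mask = np.abs(residual) > threshold_sd * sd
    outlier_idx = np.nonzero(mask)[0]
    directions = [
        "over_destabilizing" if residual[i] > 0 else "over_stabilizing"
        for i in outlier_idx
    ]

    all_letters = [l for r in records for l in _record_mut_letters(r)]
    n_all = len(all_letters)
    tests: list[ClassTest] = []
    for direction in ("over_destabilizing", "over_stabilizing"):
        letters = [
            l
            for i, d in zip(outlier_idx, directions)
            if d == direction
            for l in _record_mut_letters(records[i])
        ]
        n = len(letters)
        if n == 0:
            continue
        for name, members in classes.items():
            p0 = sum(l in members for l in all_letters) / n_all
            k = sum(l in members for l in letters)
            if p0 in (0.0, 1.0):
                continue  # class absent (or universal) in the evaluated set
            status = "enriched" if k >= n * p0 else "depleted"
            tests.append(ClassTest(
                direction=direction,
                residue_class=name,
                observed_k=k,
                n=n,
                background_p=p0,
                p_value=binomial_tail(k, n, p0, status),
                status=status,
            ))
    if holm and tests:
        order = np.argsort([t.p_value for t in tests])
        m = len(tests)
        adjusted = {}
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * tests[idx].p_value)
            adjusted[idx] = min(1.0, running)
        tests = [
            ClassTest(**{**t.__dict__, "p_adjusted": adjusted[i]})
            for i, t in enumerate(tests)
        ]

    return EnrichmentReport(
        outlier_indices=outlier_idx,
        directions=directions,
        class_tests=tests,
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=sd,
        threshold_sd=threshold_sd,
    )


def write_scatter_csv(report: EvalReport, path: str | Path, threshold_sd: float = 1.0) -> None:
    """Flat per-record CSV (exp, pred, residual, outlier flag) for plotting."""
    if report.scatter is None:
        raise ValueError("report carries no scatter table")
    df = report.scatter.copy()
    slope, intercept = np.polyfit(df["exp"], df["pred"], 1)
    fit_resid = df["pred"] - (slope * df["exp"] + intercept)
    df["outlier"] = np.abs(fit_resid) > threshold_sd * fit_resid.std(ddof=0)
    df.to_csv(path, index=False)
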