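"""Person-level cross-validation, Cohen's kappa and summaries.

The cohort of 12 persons is split into every 8-person development /
4-person validation partition (C(12,4) = 495).  For each split the
discriminant is fit on the development persons' sequences and evaluated
on the validation persons', stratified by sequence duration.  Agreement
between predicted and true mode is measured with Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e)

(p_o observed agreement, p_e chance agreement from the confusion-matrix
marginals; kappa := 0 when p_e = 1) and with the raw observed
agreement.  The *main* analysis keeps only splits where every transport
mode occurs on both sides; a *sensitivity* analysis relaxes the
validation-side requirement, which admits degenerate single-mode
validation sets (kappa 0 despite high agreement).  Summaries report the
median and IQR of kappa over splits per metric combination, class
scheme and duration stratum.

In the three-class scheme train, bus and car are collapsed into one
"motorized" label *before* model fitting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence as TySequence

import numpy as np
import pandas as pd

from .classifier import ClassifierConfig, class_sort_key, fit
from .errors import ConfigError, DataError
from .features import METRIC_NAMES, percentile
from .segmentation import STRATUM_LABELS

SCHEMES = ("five_class", "three_class")
_MOTORIZED = frozenset({"train", "bus", "car"})


def collapse_motorized(label: str) -> str:
    """Map train/bus/car to 'motorized'; walk and bike are unchanged."""
    return "motorized" if label in _MOTORIZED else label


def scheme_labels(labels: TySequence[str], scheme: str) -> np.ndarray:
    if scheme == "five_class":
        return np.asarray(labels, dtype=object)
    if scheme == "three_class":
        return np.array([collapse_motorized(str(v)) for v in labels], dtype=object)
    raise ConfigError(f"unknown class scheme {scheme!r}")


@dataclass(frozen=True)
class SplitPlan:
    """One development/validation partition of the cohort."""

    dev_persons: tuple[str, ...]
    val_persons: tuple[str, ...]
    valid_dev: bool
    valid_val: bool


def person_mode_map(
    features: pd.DataFrame, scheme: str = "five_class"
) -> dict[str, frozenset[str]]:
    """Modes contributed by each person, under the given class scheme."""
    labels = scheme_labels(features["mode"].tolist(), scheme)
    out: dict[str, set[str]] = {}
    for pid, lab in zip(features["person_id"].astype(str), labels):
        out.setdefault(pid, set()).add(lab)
    return {p: frozenset(m) for p, m in out.items()}


def enumerate_splits(
    person_modes: Mapping[str, frozenset[str]], val_size: int = 4
) -> list[SplitPlan]:
    """All unordered dev/val partitions with coverage flags.

    ``valid_dev``/``valid_val`` record whether every mode in the cohort
    occurs among the respective side's sequences.  Ordering is
    lexicographic by the sorted validation set.
    """
    persons = sorted(person_modes)
    n = len(persons)
    if val_size <= 0 or val_size >= n:
        raise ConfigError(
            f"val_size must lie strictly between 0 and {n}, got {val_size}"
        )
    all_modes = frozenset().union(*person_modes.values())
    splits = []
    for val in itertools.combinations(persons, val_size):
        dev = tuple(p for p in persons if p not in val)
        dev_modes = frozenset().union(*(person_modes[p] for p in dev))
        val_modes = frozenset().union(*(person_modes[p] for p in val))
        splits.append(
            SplitPlan(
                dev_persons=dev,
                val_persons=val,
                valid_dev=dev_modes == all_modes,
                valid_val=val_modes == all_modes,
            )
        )
    return splits


def metric_combinations(
    metric_names: TySequence[str] = METRIC_NAMES, max_size: int = 3
) -> list[tuple[str, ...]]:
    """All metric subsets of size 1..max_size, in deterministic order."""
    if max_size not in (1, 2, 3):
        raise ConfigError(f"max_size must be 1, 2 or 3, got {max_size}")
    out: list[tuple[str, ...]] = []
    for size in range(1, min(max_size, len(metric_names)) + 1):
        out.extend(itertools.combinations(metric_names, size))
    return out


@dataclass(frozen=True)
class ConfusionTable:
    """K x K confusion counts, rows = true, columns = predicted."""

    classes: tuple[str, ...]
    counts: np.ndarray

    @classmethod
    def from_labels(
        cls,
        true: TySequence[str],
        pred: TySequence[str],
        classes: TySequence[str] | None = None,
    ) -> "ConfusionTable":
        true = np.asarray(true, dtype=object)
        pred = np.asarray(pred, dtype=object)
        if true.shape != pred.shape:
            raise DataError("true/pred label lists differ in length")
        if classes is None:
            classes = sorted(set(true) | set(pred), key=class_sort_key)
        classes = tuple(classes)
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(true, pred):
            counts[index[t], index[p]] += 1
        return cls(classes=classes, counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _as_counts(confusion) -> np.ndarray:
    counts = confusion.counts if isinstance(confusion, ConfusionTable) else confusion
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise DataError("confusion table must be square")
    if counts.sum() < 1:
        raise DataError("confusion table is empty")
    return counts


def observed_agreement(confusion) -> float:
    """Proportion of sequences on the confusion diagonal."""
    counts = _as_counts(confusion)
    return float(np.trace(counts) / counts.sum())


def cohens_kappa(confusion) -> float:
    """Chance-corrected agreement (p_o - p_e)/(1 - p_e).

    p_e is the agreement expected from the marginals.  When p_e = 1
    (all mass in a single cell) kappa is defined as 0: a degenerate
    single-class table shows no agreement beyond chance.
    """
    counts = _as_counts(confusion)
    n = counts.sum()
    p_o = np.trace(counts) / n
    p_e = float(np.sum(counts.sum(axis=1) * counts.sum(axis=0)) / n**2)
    if p_e >= 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass(frozen=True)
class EvaluationResult:
    """Kappa and agreement for one (split, combination, scheme, stratum)."""

    split: SplitPlan
    combination: tuple[str, ...]
    scheme: str
    stratum: str  # one of STRATUM_LABELS or "all"
    kappa: float
    observed_agreement: float
    n_sequences: int


@dataclass(frozen=True)
class SummaryRow:
    """Median/IQR of kappa over splits for one evaluation cell."""

    combination: tuple[str, ...]
    scheme: str
    stratum: str
    n_splits: int
    kappa_median: float
    kappa_q25: float
    kappa_q75: float
    agreement_median: float


@dataclass(frozen=True)
class EvalConfig:
    """Cross-validation configuration.

    ``stratum_matched_training`` switches from the default (fit on dev
    sequences of all durations, evaluate per stratum) to fitting one
    model per stratum on that stratum's dev sequences.
    """

    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    val_size: int = 4
    stratum_matched_training: bool = False


def _evaluate_block(split, combination, scheme, val_labels, preds, stratum_mask, stratum):
    true = val_labels[stratum_mask]
    pred = preds[stratum_mask]
    classes = sorted(set(true) | set(pred), key=class_sort_key)
    ct = ConfusionTable.from_labels(true, pred, classes)
    return EvaluationResult(
        split=split,
        combination=combination,
        scheme=scheme,
        stratum=stratum,
        kappa=cohens_kappa(ct),
        observed_agreement=observed_agreement(ct),
        n_sequences=int(stratum_mask.sum()),
    )


def evaluate_split(
    split: SplitPlan,
    combination: TySequence[str],
    scheme: str,
    features: pd.DataFrame,
    config: EvalConfig | None = None,
) -> list[EvaluationResult]:
    """Fit on the split's development persons, evaluate per stratum.

    Returns one result per duration stratum with validation sequences,
    plus the pooled "all" row.  A split whose development side lacks a
    mode (under the scheme) cannot be fit and yields an empty list.
    """
    config = config or EvalConfig()
    combination = tuple(combination)
    labels = scheme_labels(features["mode"].tolist(), scheme)
    persons = features["person_id"].astype(str).to_numpy()
    dev_mask = np.isin(persons, split.dev_persons)
    val_mask = np.isin(persons, split.val_persons)
    all_classes = set(labels)
    if set(labels[dev_mask]) != all_classes:
        return []
    if not val_mask.any():
        return []

    val_df = features.loc[val_mask]
    val_labels = labels[val_mask]
    strata = val_df["stratum"].to_numpy()
    results: list[EvaluationResult] = []

    if not config.stratum_matched_training:
        model = fit(features.loc[dev_mask], labels[dev_mask], combination, config.classifier)
        preds = np.atleast_1d(model.predict(val_df[list(combination)].to_numpy(float)))
        for stratum in ("all",) + STRATUM_LABELS:
            mask = np.ones(len(val_df), bool) if stratum == "all" else strata == stratum
            if not mask.any():
                continue
            results.append(
                _evaluate_block(split, combination, scheme, val_labels, preds, mask, stratum)
            )
    else:
        dev_df = features.loc[dev_mask]
        dev_strata = dev_df["stratum"].to_numpy()
        dev_labels = labels[dev_mask]
        for stratum in ("all",) + STRATUM_LABELS:
            d_mask = np.ones(len(dev_df), bool) if stratum == "all" else dev_strata == stratum
            v_mask = np.ones(len(val_df), bool) if stratum == "all" else strata == stratum
            if not v_mask.any() or len(set(dev_labels[d_mask])) < 2:
                continue
            model = fit(
                dev_df.loc[d_mask], dev_labels[d_mask], combination, config.classifier
            )
            preds = np.atleast_1d(
                model.predict(val_df[list(combination)].to_numpy(float))
            )
            results.append(
                _evaluate_block(split, combination, scheme, val_labels, preds, v_mask, stratum)
            )
    return results


def summarize(results: Iterable[EvaluationResult]) -> list[SummaryRow]:
    """Median and IQR (type-7) of kappa over splits per evaluation cell."""
    groups: dict[tuple, list[EvaluationResult]] = {}
    for r in results:
        groups.setdefault((r.combination, r.scheme, r.stratum), []).append(r)
    rows = []
    for (combination, scheme, stratum), rs in sorted(
        groups.items(), key=lambda kv: (kv[0][1], kv[0][0], kv[0][2])
    ):
        kappas = [r.kappa for r in rs]
        rows.append(
            SummaryRow(
                combination=combination,
                scheme=scheme,
                stratum=stratum,
                n_splits=len(rs),
                kappa_median=percentile(kappas, 0.5),
                kappa_q25=percentile(kappas, 0.25),
                kappa_q75=percentile(kappas, 0.75),
                agreement_median=percentile([r.observed_agreement for r in rs], 0.5),
            )
        )
    return rows


def run_crossval(
    features: pd.DataFrame,
    splits: TySequence[SplitPlan] | None = None,
    combinations: TySequence[TySequence[str]] | None = None,
    scheme: str = "five_class",
    config: EvalConfig | None = None,
    require_valid_val: bool = True,
) -> tuple[list[EvaluationResult], list[SummaryRow]]:
    """Exhaustive combination search under person-level cross-validation.

    The main analysis keeps splits where every mode (under the scheme)
    occurs on both sides.  Coverage flags are recomputed here for the
    active scheme, so ``splits`` enumerated under another scheme can be
    reused safely.
    """
    config = config or EvalConfig()
    pm = person_mode_map(features, scheme)
    if splits is None:
        splits = enumerate_splits(pm, config.val_size)
    else:
        all_modes = frozenset().union(*pm.values())
        splits = [
            replace(
                s,
                valid_dev=frozenset().union(
                    *(pm.get(p, frozenset()) for p in s.dev_persons)
                )
                == all_modes,
                valid_val=frozenset().union(
                    *(pm.get(p, frozenset()) for p in s.val_persons)
                )
                == all_modes,
            )
            for s in splits
        ]
    selected = [
        s for s in splits if s.valid_dev and (s.valid_val or not require_valid_val)
    ]
    if not selected:
        warnings.warn(
            "no split has the required mode coverage; summaries will be empty",
            stacklevel=2,
        )
    if combinations is None:
        combinations = metric_combinations(METRIC_NAMES, 3)
    results: list[EvaluationResult] = []
    for combination in combinations:
        for s in selected:
            results.extend(evaluate_split(s, combination, scheme, features, config))
    return results, summarize(results)


def run_sensitivity(
    features: pd.DataFrame,
    splits: TySequence[SplitPlan] | None = None,
    combinations: TySequence[TySequence[str]] | None = None,
    scheme: str = "five_class",
    config: EvalConfig | None = None,
) -> tuple[list[EvaluationResult], list[SummaryRow]]:
    """As :func:`run_crossval` but requiring mode coverage only on the
    development side (admits degenerate validation sets)."""
    return run_crossval(
        features, splits, combinations, scheme, config, require_valid_val=False
    )


def observation_time_share(durations, min_duration: int = 60) -> float:
    """Share of total observation time in sequences longer than the cut.

    ``durations`` may be an iterable of sequence durations (seconds) or
    a feature table with a ``duration_s`` column.
    """
    if isinstance(durations, pd.DataFrame):
        durations = durations["duration_s"].to_numpy()
    arr = np.asarray(list(durations), dtype=float)
    if arr.size == 0:
        raise DataError("observation_time_share of an empty sequence table")
    return float(arr[arr > min_duration].sum() / arr.sum())


# ---------------------------------------------------------------------------
# Tabular export

def results_to_frame(results: Iterable[EvaluationResult]) -> pd.DataFrame:
    rows = [
        {
            "scheme": r.scheme,
            "combination": "+".join(r.combination),
            "stratum": r.stratum,
            "dev_persons": "|".join(r.split.dev_persons),
            "val_persons": "|".join(r.split.val_persons),
            "valid_val": r.split.valid_val,
            "kappa": r.kappa,
            "observed_agreement": r.observed_agreement,
            "n_sequences": r.n_sequences,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "scheme",
            "combination",
            "stratum",
            "dev_persons",
            "val_persons",
            "valid_val",
            "kappa",
            "observed_agreement",
            "n_sequences",
        ],
    )


def summary_to_frame(rows: Iterable[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scheme": r.scheme,
                "combination": "+".join(r.combination),
                "stratum": r.stratum,
                "n_splits": r.n_splits,
                "kappa_median": r.kappa_median,
                "kappa_q25": r.kappa_q25,
                "kappa_q75": r.kappa_q75,
                "agreement_median": r.agreement_median,
            }
            for r in rows
        ],
        columns=[
            "scheme",
            "combination",
            "stratum",
            "n_splits",
            "kappa_median",
            "kappa_q25",
            "kappa_q75",
            "agreement_median",
        ],
    )
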