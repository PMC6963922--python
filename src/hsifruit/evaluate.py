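"""Sample splitting, confusion matrices, accuracy and report tables."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ReportError, SplitCountError

SPLIT_NAMES = ("calibration", "validation", "prediction")
ORIGIN_NAMES = ("Gansu", "Ningxia", "Xinjiang")

#: per-class (calibration, validation, prediction) counts of the study
PAPER_SPLIT_COUNTS: dict[int, tuple[int, int, int]] = {
    0: (539, 291, 275),
    1: (602, 303, 300),
    2: (481, 241, 240),
}
PAPER_CLASS_TOTALS = (1105, 1205, 962)


@dataclass
class SplitAssignment:
    """Per-sample split names plus the counts they were built from."""

    assignment: np.ndarray  # array of split names, one per sample
    counts: dict[int, tuple[int, int, int]]
    seed: int

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.assignment == split)


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = true origin, columns = predicted origin."""

    counts: np.ndarray
    split: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 3x3 with non-negative counts")


def proportional_split_counts(
    class_totals: tuple[int, int, int],
    reference: dict[int, tuple[int, int, int]] | None = None,
) -> dict[int, tuple[int, int, int]]:
    """Scale the study's per-class split fractions to new class totals.

    Largest-remainder rounding keeps each class's three counts summing to
    its total exactly.
    """
    reference = reference or PAPER_SPLIT_COUNTS
    out: dict[int, tuple[int, int, int]] = {}
    for c, total in enumerate(class_totals):
        ref = np.asarray(reference[c], dtype=float)
        exact = ref / ref.sum() * total
        base = np.floor(exact).astype(int)
        short = total - base.sum()
        order = np.argsort(-(exact - base))
        base[order[:short]] += 1
        out[c] = tuple(int(v) for v in base)
    return out


def split_samples(
    labels: np.ndarray,
    counts: dict[int, tuple[int, int, int]],
    seed: int,
) -> SplitAssignment:
    """Stratified random split with exact per-class counts, seeded."""
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.size, dtype=object)
    for c, split_counts in counts.items():
        members = np.flatnonzero(labels == c)
        if sum(split_counts) != members.size:
            raise SplitCountError(
                f"class {c}: split counts {split_counts} sum to {sum(split_counts)} "
                f"but the class has {members.size} samples"
            )
        members = rng.permutation(members)
        edges = np.cumsum((0,) + tuple(split_counts))
        for name, lo, hi in zip(SPLIT_NAMES, edges[:-1], edges[1:]):
            assignment[members[lo:hi]] = name
    return SplitAssignment(assignment=assignment, counts=dict(counts), seed=seed)


def confusion(y_true: np.ndarray, y_pred: np.ndarray, split: str = "") -> ConfusionMatrix:
    """Tally a 3x3 confusion matrix (rows true, columns predicted)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size != y_pred.size:
        raise ValueError("true/predicted label lengths differ")
    for arr, what in ((y_true, "true"), (y_pred, "predicted")):
        bad = ~np.isin(arr, (0, 1, 2))
        if bad.any():
            raise ValueError(f"{what} labels outside {{0,1,2}}: {np.unique(arr[bad])}")
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts=counts, split=split)


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent of correctly classified samples (full precision)."""
    total = int(cm.counts.sum())
    if total == 0:
        raise EmptyInputError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / total


def round2(value: float) -> float:
    """Half-up rounding to two decimals, for presentation only."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def report(
    results: dict[str, dict[str, dict[str, ConfusionMatrix]]],
    outdir: str | Path,
) -> pd.DataFrame:
    """Emit per-model confusion/accuracy tables.

    ``results[feature_set][model][split]`` holds a :class:`ConfusionMatrix`.
    Writes one CSV per feature set mirroring the study's table layout and
    returns a tidy accuracy frame (also written as ``accuracy.csv``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tidy_rows = []
    for feature_set, per_model in results.items():
        lines = []
        for model_name, per_split in per_model.items():
            missing = [s for s in SPLIT_NAMES if s not in per_split]
            if missing:
                raise ReportError(
                    f"{feature_set}/{model_name}: missing splits {missing}"
                )
            for true_class in range(3):
                row = [model_name if true_class == 0 else "", str(true_class)]
                for split in SPLIT_NAMES:
                    row += [str(int(v)) for v in per_split[split].counts[true_class]]
                lines.append(",".join(row))
            totals = [model_name, "Total (%)"]
            for split in SPLIT_NAMES:
                acc = round2(accuracy(per_split[split]))
                totals += ["", "", f"{acc:.2f}"]
                tidy_rows.append(
                    {
                        "feature_set": feature_set,
                        "model": model_name,
                        "split": split,
                        "accuracy_pct": acc,
                    }
                )
            lines.append(",".join(totals))
        header = "model,category," + ",".join(
            f"{s}_{c}" for s in SPLIT_NAMES for c in ("0", "1", "2")
        )
        (outdir / f"confusion_{feature_set}.csv").write_text(header + "\n" + "\n".join(lines) + "\n")
    tidy = pd.DataFrame(tidy_rows)
    tidy.to_csv(outdir / "accuracy.csv", index=False)
    return tidy
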