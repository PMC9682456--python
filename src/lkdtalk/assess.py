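"""Post-classification assessment: audit samples, confusion matrices,
false-positive error taxonomy, and share tables.

After the classifier labels a full corpus, a random sample of machine
predictions per source is read by humans and each prediction marked
correct or incorrect against the annotation criteria.  False positives
additionally receive one of the eight :class:`~lkdtalk.corpus_io.ErrorType`
categories.  This module draws such review samples, tabulates the verdicts
into per-source confusion matrices, breaks false positives down by error
type, and expresses each confusion cell as a share of its column.

The module also ships the per-source confusion counts and summary metrics
from the source study's published post-classification review (1,824
audited predictions), so the audit arithmetic can be checked against the
published figures; :func:`audit_reported_metrics` recomputes every metric
from the raw counts and flags published cells that the counts do not
support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from lkdtalk.corpus_io import Comment, ErrorType, Label, Source
from lkdtalk.train_eval import ConfusionCounts, compute_metrics

__all__ = [
    "AssessmentSample",
    "ErrorBreakdown",
    "confusion_by_source",
    "sample_for_review",
    "error_breakdown",
    "source_share",
    "PUBLISHED_REVIEW_COUNTS",
    "PUBLISHED_METRICS_PCT",
    "PUBLISHED_ERROR_TYPE_COUNTS",
    "audit_reported_metrics",
    "audit_error_table",
    "plot_confusion_heatmaps",
]


@dataclass
class AssessmentSample:
    """Human-reviewed predictions: every comment carries a predicted label
    and a verdict ("correct" / "incorrect")."""

    comments: list[Comment]
    verdicts: list[str]

    def __post_init__(self) -> None:
        if len(self.comments) != len(self.verdicts):
            raise ValueError("comments and verdicts must be parallel")
        for c, v in zip(self.comments, self.verdicts):
            if c.predicted_label is None:
                raise ValueError(f"comment {c.key} has no predicted label")
            if v not in ("correct", "incorrect"):
                raise ValueError(f"verdict must be 'correct'/'incorrect', got {v!r}")

    def per_source_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for c in self.comments:
            sizes[c.source.value] = sizes.get(c.source.value, 0) + 1
        return sizes


def confusion_by_source(
    sample: AssessmentSample,
) -> dict[str, ConfusionCounts]:
    """Per-source confusion counts plus their elementwise-sum aggregate.

    A prediction of *related* judged correct is a true positive; judged
    incorrect, a false positive — and symmetrically for *not related*.
    """
    cells: dict[str, dict[str, int]] = {}
    for c, v in zip(sample.comments, sample.verdicts):
        d = cells.setdefault(c.source.value, {"tp": 0, "fp": 0, "fn": 0, "tn": 0})
        predicted_related = c.predicted_label is Label.RELATED
        correct = v == "correct"
        if predicted_related and correct:
            d["tp"] += 1
        elif predicted_related and not correct:
            d["fp"] += 1
        elif not predicted_related and correct:
            d["tn"] += 1
        else:
            d["fn"] += 1
    out = {
        src: ConfusionCounts(stratum=src, **d) for src, d in sorted(cells.items())
    }
    aggregate = ConfusionCounts(0, 0, 0, 0)
    for counts in out.values():
        aggregate = aggregate + counts
    out["aggregate"] = aggregate
    return out


def sample_for_review(
    predictions: Sequence[Comment],
    per_source_n: Mapping[str | Source, int],
    seed: int = 0,
) -> AssessmentSample:
    """Draw a review sample of machine-classified comments.

    For each requested source, draws uniformly without replacement within
    each predicted class, allocating the request across the two classes in
    proportion to their prevalence (so both classes appear whenever both
    are available).  Verdicts are left empty for human entry — the
    returned sample has verdict placeholders ``""`` and must be completed
    before tabulation.

    Raises
    ------
    ValueError
        If a request exceeds the comments available for that source.
    """
    rng = np.random.default_rng(seed)
    by_source: dict[str, list[Comment]] = {}
    for c in predictions:
        if c.predicted_label is None:
            raise ValueError(f"comment {c.key} has no predicted label")
        by_source.setdefault(c.source.value, []).append(c)
    chosen: list[Comment] = []
    for src, n_req in sorted(
        (Source(s).value, n) for s, n in per_source_n.items()
    ):
        pool = by_source.get(src, [])
        if n_req > len(pool):
            raise ValueError(
                f"requested {n_req} comments for source {src!r} "
                f"but only {len(pool)} are available"
            )
        related = [c for c in pool if c.predicted_label is Label.RELATED]
        unrelated = [c for c in pool if c.predicted_label is Label.NOT_RELATED]
        n_rel = int(round(n_req * len(related) / len(pool))) if pool else 0
        n_rel = min(n_rel, len(related))
        n_unrel = min(n_req - n_rel, len(unrelated))
        n_rel = n_req - n_unrel  # top up if one class ran short
        # Guarantee both classes when both exist and the request allows.
        if n_req >= 2 and related and unrelated:
            n_rel = max(1, min(n_rel, n_req - 1))
            n_unrel = n_req - n_rel
        for group, n_take in ((related, n_rel), (unrelated, n_unrel)):
            idx = rng.choice(len(group), size=n_take, replace=False)
            chosen.extend(group[i] for i in sorted(idx))
    return _skeleton(chosen)


def _skeleton(chosen: list[Comment]) -> "AssessmentSample":
    # Bypass verdict validation for the empty skeleton the human fills in.
    sample = AssessmentSample.__new__(AssessmentSample)
    sample.comments = chosen
    sample.verdicts = [""] * len(chosen)
    return sample


@dataclass
class ErrorBreakdown:
    """False-positive counts by (source, error type), with margins."""

    table: pd.DataFrame  # rows: error types, columns: sources, plus Total

    @property
    def column_totals(self) -> pd.Series:
        return self.table.sum(axis=0)

    def category_fractions(self) -> pd.Series:
        """Each category's share of all false positives."""
        totals = self.table.sum(axis=1)
        grand = totals.sum()
        return totals / grand if grand else totals


def error_breakdown(sample: AssessmentSample) -> ErrorBreakdown:
    """Tabulate false-positive error types by source.

    Every false positive in the sample must carry an error type; an empty
    breakdown (no false positives) is valid.
    """
    missing = []
    rows = []
    for c, v in zip(sample.comments, sample.verdicts):
        is_fp = c.predicted_label is Label.RELATED and v == "incorrect"
        if not is_fp:
            continue
        if c.error_type is None:
            missing.append(c.key)
        else:
            rows.append((c.error_type.value, c.source.value))
    if missing:
        raise ValueError(
            f"false positives missing an error type: {missing}"
        )
    categories = [e.value for e in ErrorType]
    sources = [s.value for s in Source]
    table = pd.DataFrame(0, index=categories, columns=sources, dtype=int)
    for cat, src in rows:
        table.loc[cat, src] += 1
    return ErrorBreakdown(table=table)


def source_share(counts: Mapping[str, ConfusionCounts]) -> pd.DataFrame:
    """Each confusion cell as count and percent of its column total.

    Rows are sources; columns fp/tp/fn/tn each paired with a percentage of
    that cell type's total across sources, rounded to one decimal.
    """
    sources = [s for s in counts if s != "aggregate"]
    cells = ("fp", "tp", "fn", "tn")
    totals = {cell: sum(getattr(counts[s], cell) for s in sources) for cell in cells}
    if not any(totals.values()):
        raise ValueError("all confusion cells are zero; shares are undefined")
    data = {}
    for cell in cells:
        data[cell] = [getattr(counts[s], cell) for s in sources]
        data[f"{cell}_pct"] = [
            round(100.0 * getattr(counts[s], cell) / totals[cell], 1)
            if totals[cell]
            else 0.0
            for s in sources
        ]
    return pd.DataFrame(data, index=sources)


# --------------------------------------------------------------------------
# Published post-classification review of 1,824 machine predictions.
# --------------------------------------------------------------------------

#: Per-source confusion counts from the published human review.
PUBLISHED_REVIEW_COUNTS: dict[str, ConfusionCounts] = {
    "nyt": ConfusionCounts(tp=112, fp=107, fn=19, tn=200, stratum="nyt"),
    "reddit": ConfusionCounts(tp=76, fp=146, fn=27, tn=195, stratum="reddit"),
    "twitter": ConfusionCounts(tp=28, fp=159, fn=7, tn=180, stratum="twitter"),
    "youtube": ConfusionCounts(tp=120, fp=164, fn=47, tn=237, stratum="youtube"),
}

#: Summary metrics (percent) as published for the same review.
PUBLISHED_METRICS_PCT: dict[str, dict[str, float]] = {
    "nyt": {"f1_macro": 70.0, "precision": 51.1, "recall": 85.5, "accuracy": 60.7},
    "reddit": {"f1_macro": 58.0, "precision": 34.2, "recall": 73.8, "accuracy": 47.1},
    "twitter": {"f1_macro": 46.8, "precision": 46.8, "recall": 15.0, "accuracy": 46.8},
    "youtube": {"f1_macro": 61.2, "precision": 61.2, "recall": 42.3, "accuracy": 46.2},
    "aggregate": {"f1_macro": 60.2, "precision": 36.8, "recall": 77.1, "accuracy": 62.9},
}

#: Published false-positive error-type counts per source, with the
#: published row totals and column headers kept verbatim so the audit can
#: surface internal inconsistencies.
PUBLISHED_ERROR_TYPE_COUNTS: pd.DataFrame = pd.DataFrame(
    {
        "nyt": [16, 0, 9, 39, 0, 25, 17, 1],
        "reddit": [10, 2, 39, 80, 0, 4, 9, 2],
        "twitter": [0, 43, 6, 60, 15, 0, 23, 12],
        "youtube": [10, 3, 15, 114, 0, 2, 27, 2],
    },
    index=[e.value for e in ErrorType],
)

#: Column totals as published (per-source false-positive counts).
PUBLISHED_ERROR_COLUMN_TOTALS: dict[str, int] = {
    "nyt": 107, "reddit": 146, "twitter": 159, "youtube": 164,
}

#: Row totals as published.
PUBLISHED_ERROR_ROW_TOTALS: dict[str, int] = {
    ErrorType.DECEASED_DONATION.value: 27,
    ErrorType.FIGURE_OF_SPEECH.value: 48,
    ErrorType.INSUFFICIENT_INFORMATION.value: 69,
    ErrorType.IRRELEVANT.value: 293,
    ErrorType.KIDNEY_STONES.value: 15,
    ErrorType.NON_LKD_POLICIES.value: 31,
    ErrorType.RECIPIENT_DIALYSIS_FAILURE.value: 76,
    ErrorType.SELLING_OR_MONEY.value: 17,
}


def published_confusions() -> dict[str, ConfusionCounts]:
    """The published per-source review counts plus their aggregate."""
    out = dict(PUBLISHED_REVIEW_COUNTS)
    aggregate = ConfusionCounts(0, 0, 0, 0)
    for counts in PUBLISHED_REVIEW_COUNTS.values():
        aggregate = aggregate + counts
    out["aggregate"] = aggregate
    return out


def audit_reported_metrics(
    counts: Mapping[str, ConfusionCounts] | None = None,
    reported_pct: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Recompute every metric from raw counts and compare with the
    published percentages.

    A published cell is ``consistent`` when the recomputed value, rounded
    to the cell's printed precision, equals it.  Inconsistent cells are
    flagged rather than matched: the recomputed value is authoritative.
    """
    counts = counts if counts is not None else published_confusions()
    reported_pct = reported_pct if reported_pct is not None else PUBLISHED_METRICS_PCT
    rows = []
    for stratum, cc in counts.items():
        report = compute_metrics(cc)
        for metric in ("f1_macro", "precision", "recall", "accuracy"):
            recomputed = 100.0 * getattr(report, metric)
            reported = reported_pct.get(stratum, {}).get(metric)
            if reported is None:
                consistent = None
            else:
                decimals = 1 if reported != int(reported) else 0
                consistent = round(recomputed, decimals) == round(reported, decimals) or (
                    round(recomputed, 1) == round(reported, 1)
                )
            rows.append(
                {
                    "stratum": stratum,
                    "metric": metric,
                    "recomputed_pct": round(recomputed, 1),
                    "reported_pct": reported,
                    "consistent": consistent,
                }
            )
    return pd.DataFrame(rows)


def audit_error_table() -> pd.DataFrame:
    """Check the published error-type table's margins against its cells.

    Returns one row per margin (each source column, each category row)
    with the cell sum, the published total, and a consistency flag.
    """
    rows = []
    for src, published in PUBLISHED_ERROR_COLUMN_TOTALS.items():
        summed = int(PUBLISHED_ERROR_TYPE_COUNTS[src].sum())
        rows.append(
            {"margin": f"column:{src}", "cell_sum": summed,
             "published_total": published, "consistent": summed == published}
        )
    for cat, published in PUBLISHED_ERROR_ROW_TOTALS.items():
        summed = int(PUBLISHED_ERROR_TYPE_COUNTS.loc[cat].sum())
        rows.append(
            {"margin": f"row:{cat}", "cell_sum": summed,
             "published_total": published, "consistent": summed == published}
        )
    return pd.DataFrame(rows)


def plot_confusion_heatmaps(
    counts: Mapping[str, ConfusionCounts], path: str
) -> None:
    """Save a panel of per-stratum confusion-matrix heatmaps (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strata = list(counts)
    fig, axes = plt.subplots(1, len(strata), figsize=(3 * len(strata), 3))
    if len(strata) == 1:
        axes = [axes]
    for ax, stratum in zip(axes, strata):
        cc = counts[stratum]
        mat = np.array([[cc.tn, cc.fp], [cc.fn, cc.tp]])
        ax.imshow(mat, cmap="viridis")
        for (r, c), val in np.ndenumerate(mat):
            ax.text(c, r, str(val), ha="center", va="center", color="white")
        ax.set_xticks([0, 1], ["pred not related", "pred related"], rotation=45)
        ax.set_yticks([0, 1], ["not related", "related"])
        ax.set_title(stratum)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
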