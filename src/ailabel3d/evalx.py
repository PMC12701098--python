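"""Evaluation machinery: overlap metrics, intra-cluster homogeneity, and the
blind-evaluation randomization/tally harness.

Human judgment itself is out of scope; ``blind_trials`` prepares the
randomized, origin-hidden presentation and ``tally`` aggregates recorded
choices with a >= 2-of-3 majority rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IncompleteDataError
from .io_prep import VolumePair, znormalize

__all__ = [
    "SegMetrics",
    "HomogeneityReport",
    "BlindTrial",
    "dice",
    "fnr",
    "fpr",
    "label_overlap",
    "overlap_summary",
    "seg_metrics",
    "intra_cluster_homogeneity",
    "blind_trials",
    "rater_view",
    "tally",
]


@dataclass(frozen=True)
class SegMetrics:
    dsc: float
    fnr: float
    fpr: float


def _as_bool_pair(pred, ref):
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    return pred, ref


def dice(pred, ref) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    pred, ref = _as_bool_pair(pred, ref)
    denom = int(pred.sum()) + int(ref.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pred & ref).sum()) / denom


def fnr(pred, ref) -> float:
    """Miss rate FN/(FN+TP) over reference-positive voxels; 0 when ref is empty."""
    pred, ref = _as_bool_pair(pred, ref)
    positives = int(ref.sum())
    if positives == 0:
        return 0.0
    return int((ref & ~pred).sum()) / positives


def fpr(pred, ref) -> float:
    """False-alarm rate FP/(FP+TN) over reference-negative voxels; 0 when ref covers all."""
    pred, ref = _as_bool_pair(pred, ref)
    negatives = int((~ref).sum())
    if negatives == 0:
        return 0.0
    return int((pred & ~ref).sum()) / negatives


def seg_metrics(pred, ref) -> SegMetrics:
    return SegMetrics(dsc=dice(pred, ref), fnr=fnr(pred, ref), fpr=fpr(pred, ref))


def label_overlap(a, b) -> float:
    """Per-case overlap between two labels, measured as Dice."""
    return dice(a, b)


def overlap_summary(pairs) -> tuple[float, float]:
    """Mean and (population) SD of per-case label overlap over a cohort."""
    values = [label_overlap(a, b) for a, b in pairs]
    if not values:
        raise ValueError("no mask pairs")
    return float(np.mean(values)), float(np.std(values))


@dataclass
class HomogeneityReport:
    """Pooled intensity variance per (cluster label, modality), plus a ranking
    of labels by mean variance across the two modalities (descending)."""

    variances: dict[tuple[int, str], float]
    undefined: set[int]
    cluster_ranking: list[int]


def intra_cluster_homogeneity(cluster_maps, pairs, exclude=frozenset()) -> HomogeneityReport:
    """Population variance of z-normalized intensities within each cluster,
    pooled across cases, for both modalities.

    Labels in ``exclude`` (typically background clusters) are skipped; labels
    with fewer than 2 pooled voxels are flagged as undefined and left out of
    the ranking.  The result is invariant to case ordering.
    """
    cluster_maps = list(cluster_maps)
    pairs = list(pairs)
    if len(cluster_maps) != len(pairs):
        raise ValueError("cluster_maps and pairs must be case-aligned")
    if not cluster_maps:
        raise ValueError("empty input")

    pooled: dict[tuple[int, str], list[np.ndarray]] = {}
    for cmap, pair in zip(cluster_maps, pairs):
        cmap = np.asarray(cmap)
        if cmap.shape != pair.shape:
            raise ValueError("cluster map and volume shapes differ")
        zvols = {"t1": znormalize(pair.t1), "t2": znormalize(pair.t2)}
        for lab in np.unique(cmap):
            lab = int(lab)
            if lab in exclude:
                continue
            vox = cmap == lab
            for mod, z in zvols.items():
                pooled.setdefault((lab, mod), []).append(z[vox])

    variances: dict[tuple[int, str], float] = {}
    undefined: set[int] = set()
    labels = sorted({lab for lab, _ in pooled})
    for lab in labels:
        for mod in ("t1", "t2"):
            values = np.concatenate(pooled.get((lab, mod), [np.empty(0)]))
            if values.size < 2:
                variances[(lab, mod)] = float("nan")
                undefined.add(lab)
            else:
                variances[(lab, mod)] = float(values.var())

    ranked = [lab for lab in labels if lab not in undefined]
    ranked.sort(key=lambda lab: -(variances[(lab, "t1")] + variances[(lab, "t2")]) / 2.0)
    return HomogeneityReport(variances=variances, undefined=undefined, cluster_ranking=ranked)


@dataclass
class BlindTrial:
    """One case of the blind comparison.  ``presentation_order`` lists the model
    keys ("A"/"B") in display order and ``color_assignment`` maps model key to
    display color; both constitute the un-blinding key and must not be shown
    to raters (see :func:`rater_view`)."""

    case_id: str
    presentation_order: tuple[str, str]
    color_assignment: dict
    choices: dict = field(default_factory=dict)  # rater -> model key
    majority: str | None = None


_COLORS = ("red", "blue")


def blind_trials(preds_a, preds_b, rng_seed: int = 0, case_ids=None) -> list[BlindTrial]:
    """Prepare one randomized trial per case: independent order permutation and
    color assignment, deterministic given ``rng_seed``."""
    preds_a, preds_b = list(preds_a), list(preds_b)
    if len(preds_a) != len(preds_b):
        raise ValueError("prediction lists must be case-aligned and equal length")
    if case_ids is None:
        case_ids = [f"case_{i:03d}" for i in range(len(preds_a))]
    rng = np.random.default_rng(rng_seed)
    trials = []
    for cid in case_ids:
        order = ("A", "B") if rng.random() < 0.5 else ("B", "A")
        colors = list(_COLORS)
        rng.shuffle(colors)
        trials.append(BlindTrial(
            case_id=str(cid),
            presentation_order=order,
            color_assignment={"A": colors[0], "B": colors[1]},
        ))
    return trials


def rater_view(trial: BlindTrial) -> dict:
    """The rater-facing record: colors in display order, no model identifiers."""
    return {
        "case_id": trial.case_id,
        "display_colors": [trial.color_assignment[m] for m in trial.presentation_order],
    }


def tally(trials: list[BlindTrial]) -> dict:
    """Aggregate recorded choices.

    Returns per-rater counts, per-model totals and percentages, per-case
    majority (model chosen by >= 2 of 3 raters; "none" on a tie with even
    rater counts) and agreement statistics.
    """
    if not trials:
        raise ValueError("no trials")
    raters = sorted({r for t in trials for r in t.choices})
    if not raters:
        raise IncompleteDataError("no choices recorded")
    for t in trials:
        for r in raters:
            if r not in t.choices:
                raise IncompleteDataError(f"missing choice for case {t.case_id!r}, rater {r!r}")

    models = ("A", "B")
    per_rater = {r: {m: 0 for m in models} for r in raters}
    totals = {m: 0 for m in models}
    majority_counts: dict[str, int] = {m: 0 for m in models}
    majority_counts["none"] = 0
    unanimous = 0
    split_2_1 = 0

    for t in trials:
        votes = {m: 0 for m in models}
        for r in raters:
            choice = t.choices[r]
            if choice not in models:
                raise ValueError(f"unknown model key {choice!r} for case {t.case_id!r}")
            per_rater[r][choice] += 1
            totals[choice] += 1
            votes[choice] += 1
        need = len(raters) // 2 + 1
        winner = max(models, key=lambda m: votes[m])
        if votes[winner] >= need:
            t.majority = winner
            majority_counts[winner] += 1
        else:
            t.majority = "none"
            majority_counts["none"] += 1
        if votes[winner] == len(raters):
            unanimous += 1
        elif votes[winner] == len(raters) - 1:
            split_2_1 += 1

    n_votes = len(raters) * len(trials)
    return {
        "raters": raters,
        "n_cases": len(trials),
        "per_rater": per_rater,
        "totals": totals,
        "percentages": {m: 100.0 * totals[m] / n_votes for m in models},
        "majority": majority_counts,
        "agreement": {"unanimous": unanimous, "split_2_1": split_2_1},
    }
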