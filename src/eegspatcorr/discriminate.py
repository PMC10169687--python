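"""Leave-one-subject-out discrimination from a single biomarker value.

Each held-out subject is assigned to whichever group's median biomarker
value (recomputed without that subject) is closer.  The rule is deliberately
minimal — no fitted classifier — so that discrimination performance reflects
the biomarker alone.  Chance level for two groups is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscriminationResult", "loso_discriminate", "confusion_metrics"]


@dataclass
class DiscriminationResult:
    """LOSO predictions and confusion metrics for one two-group contrast.

    ``confusion`` rows are actual (target, other), columns predicted
    (target, other).  ``sensitivity`` is the fraction of the target group
    predicted as target; ``specificity`` the fraction of the other group
    predicted as other.  Metrics undefined for an empty class are None.
    """

    contrast: tuple[str, str]
    predictions: dict[str, str]
    confusion: np.ndarray
    accuracy: float
    sensitivity: float | None
    specificity: float | None


def loso_discriminate(
    values: dict[str, float],
    labels: dict[str, str],
    contrast: tuple[str, str],
    tie: str = "other",
) -> DiscriminationResult:
    """Leave-one-subject-out median-closeness discrimination.

    ``values`` maps subject id to the biomarker value (e.g. M_psi of the
    biomarker channel pair) and ``labels`` to group membership; only the two
    groups named in ``contrast = (target, other)`` take part.  Equal
    distances are resolved to the non-target group by default (``tie`` may
    be set to ``'target'``).
    """
    target, other = contrast
    if target == other:
        raise ValueError("contrast groups must differ")
    if tie not in ("other", "target"):
        raise ValueError("tie must be 'other' or 'target'")
    members = {g: [s for s in values if labels.get(s) == g] for g in contrast}
    for g, ids in members.items():
        if len(ids) < 2:
            raise ValueError(f"group {g!r} has {len(ids)} subject(s); need >= 2")

    predictions: dict[str, str] = {}
    for subject in members[target] + members[other]:
        medians = {}
        for g in contrast:
            rest = [values[s] for s in members[g] if s != subject]
            medians[g] = float(np.median(rest))
        d_target = abs(values[subject] - medians[target])
        d_other = abs(values[subject] - medians[other])
        if d_target < d_other:
            predictions[subject] = target
        elif d_other < d_target:
            predictions[subject] = other
        else:
            predictions[subject] = target if tie == "target" else other

    accuracy, sensitivity, specificity, confusion = confusion_metrics(
        predictions, labels, target, return_confusion=True
    )
    return DiscriminationResult(
        contrast=contrast,
        predictions=predictions,
        confusion=confusion,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
    )


def confusion_metrics(
    predictions: dict[str, str],
    labels: dict[str, str],
    target: str,
    return_confusion: bool = False,
):
    """Accuracy, sensitivity and specificity of binary predictions.

    Subjects present in ``predictions`` are scored against ``labels``;
    every label other than ``target`` counts as the non-target class.  A
    metric whose class is empty is returned as None rather than 0.
    """
    tp = fn = tn = fp = 0
    for subject, predicted in predictions.items():
        actual = labels[subject]
        if actual == target:
            if predicted == target:
                tp += 1
            else:
                fn += 1
        else:
            if predicted == target:
                fp += 1
            else:
                tn += 1
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("no predictions to score")
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    if return_confusion:
        confusion = np.array([[tp, fn], [fp, tn]])
        return accuracy, sensitivity, specificity, confusion
    return accuracy, sensitivity, specificity
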