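"""Expert gold-standard construction and inter-expert reliability.

Experts rate whole 3D volumes pass/fail with a 1-5 confidence. Ratings
are recoded to a signed -5..5 scale (sign = decision, magnitude =
confidence; 0 never occurs). An image enters the gold set only when every
expert who rated it was confident (|signed score| >= threshold, default
4) and all decisions agree. Reliability is summarised as the ROC AUC of
each expert's signed scores against a reference expert's binary
decisions on commonly rated images, averaged with weights equal to the
overlap counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import UndefinedMetricError, auc_mann_whitney

__all__ = [
    "recode_signed",
    "build_gold_standard",
    "expert_reliability",
    "simulate_expert_panel",
    "GoldStandardResult",
    "ReliabilityResult",
]


def recode_signed(decision: str | int, confidence: int) -> int:
    """Recode (pass/fail, confidence 1-5) to a signed score in [-5, 5] \\ {0}."""
    conf = int(confidence)
    if not 1 <= conf <= 5:
        raise ValueError(f"confidence must be in 1..5, got {confidence}")
    if isinstance(decision, str):
        d = decision.lower()
        if d not in ("pass", "fail"):
            raise ValueError(f"decision must be 'pass' or 'fail', got {decision!r}")
        passed = d == "pass"
    elif decision in (0, 1):
        passed = bool(decision)
    else:
        raise ValueError(f"decision must be pass/fail or 0/1, got {decision!r}")
    return conf if passed else -conf


def _signed_column(ratings: pd.DataFrame) -> pd.Series:
    return ratings.apply(lambda r: recode_signed(r["decision"], r["confidence"]), axis=1)


@dataclass
class GoldStandardResult:
    labels: pd.DataFrame  # image_id, label, n_experts, min_abs_score
    n_pass: int
    n_fail: int
    n_excluded: int

    def __repr__(self) -> str:
        return (
            f"GoldStandardResult(n_pass={self.n_pass}, n_fail={self.n_fail}, "
            f"n_excluded={self.n_excluded})"
        )


def build_gold_standard(
    ratings: pd.DataFrame,
    conf_threshold: int = 4,
    require_all_experts: bool = False,
) -> GoldStandardResult:
    """Select confidently, unanimously rated images as the gold standard.

    ``ratings`` needs columns expert_id, image_id, decision, confidence.
    An image qualifies iff every expert who rated it gave a signed score
    of magnitude >= ``conf_threshold`` and all signs agree; its label is
    the shared sign mapped to {0, 1}. With ``require_all_experts`` the
    image must additionally have been rated by every expert in the table.
    """
    if not 1 <= conf_threshold <= 5:
        raise ValueError("conf_threshold must be in 1..5")
    df = ratings.copy()
    if len(df) == 0:
        return GoldStandardResult(
            labels=pd.DataFrame(columns=["image_id", "label", "n_experts", "min_abs_score"]),
            n_pass=0,
            n_fail=0,
            n_excluded=0,
        )
    df["signed"] = _signed_column(df)
    n_experts_total = df["expert_id"].nunique()

    rows = []
    n_excluded = 0
    for image_id, grp in df.groupby("image_id", sort=True):
        signed = grp["signed"].to_numpy()
        confident = (np.abs(signed) >= conf_threshold).all()
        unanimous = (signed > 0).all() or (signed < 0).all()
        complete = (not require_all_experts) or grp["expert_id"].nunique() == n_experts_total
        if confident and unanimous and complete:
            rows.append(
                {
                    "image_id": image_id,
                    "label": int(signed[0] > 0),
                    "n_experts": int(grp["expert_id"].nunique()),
                    "min_abs_score": int(np.abs(signed).min()),
                }
            )
        else:
            n_excluded += 1
    labels = pd.DataFrame(rows, columns=["image_id", "label", "n_experts", "min_abs_score"])
    return GoldStandardResult(
        labels=labels,
        n_pass=int((labels["label"] == 1).sum()) if len(labels) else 0,
        n_fail=int((labels["label"] == 0).sum()) if len(labels) else 0,
        n_excluded=n_excluded,
    )


@dataclass
class ReliabilityResult:
    weighted_auc: float
    pairs: pd.DataFrame  # expert_id, auc, n_common
    skipped: list[str] = field(default_factory=list)


def expert_reliability(
    ratings: pd.DataFrame, reference_expert: str
) -> ReliabilityResult:
    """Weighted mean AUC of each expert's signed scores vs the reference.

    For every non-reference expert the ROC AUC of their signed -5..5
    scores against the reference's binary decisions is computed on
    commonly rated images; the average is weighted by the overlap count.
    Pairs whose overlap contains a single reference class are skipped and
    reported.
    """
    df = ratings.copy()
    df["signed"] = _signed_column(df)
    if reference_expert not in set(df["expert_id"]):
        raise ValueError(f"reference expert {reference_expert!r} not in table")
    ref = df[df["expert_id"] == reference_expert].set_index("image_id")
    ref_label = (ref["signed"] > 0).astype(int)

    rows, skipped = [], []
    for expert_id, grp in df[df["expert_id"] != reference_expert].groupby("expert_id"):
        grp = grp.set_index("image_id")
        common = grp.index.intersection(ref_label.index)
        if len(common) < 2:
            skipped.append(expert_id)
            continue
        try:
            auc = auc_mann_whitney(grp.loc[common, "signed"], ref_label.loc[common])
        except UndefinedMetricError:
            skipped.append(expert_id)
            continue
        rows.append({"expert_id": expert_id, "auc": auc, "n_common": len(common)})
    pairs = pd.DataFrame(rows, columns=["expert_id", "auc", "n_common"])
    if len(pairs) == 0:
        raise UndefinedMetricError("no expert pair had both classes in common")
    weighted = float(np.average(pairs["auc"], weights=pairs["n_common"]))
    return ReliabilityResult(weighted_auc=weighted, pairs=pairs, skipped=skipped)


def simulate_expert_panel(
    image_ids,
    true_labels,
    n_experts: int = 4,
    accuracy: float = 0.97,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a small panel of highly reliable experts.

    Each expert independently gets each image right with probability
    ``accuracy``; confidence is high (4-5) when the image is far from
    ambiguous and the call is correct, lower (1-3) otherwise — a crude
    but serviceable stand-in for careful 3D inspection.
    """
    if n_experts < 1:
        raise ValueError("n_experts must be >= 1")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    rng = np.random.default_rng(seed)
    image_ids = list(image_ids)
    truth = np.asarray(true_labels, dtype=int)
    rows = []
    for e in range(n_experts):
        correct = rng.random(len(image_ids)) < accuracy
        decisions = np.where(correct, truth, 1 - truth)
        conf = np.where(correct, rng.integers(4, 6, len(image_ids)), rng.integers(1, 4, len(image_ids)))
        for img, d, c in zip(image_ids, decisions, conf):
            rows.append(
                {
                    "expert_id": f"expert{e}",
                    "image_id": img,
                    "decision": "pass" if d == 1 else "fail",
                    "confidence": int(c),
                }
            )
    return pd.DataFrame(rows)
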