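"""End-to-end orchestration: phantoms -> crowd -> amplification -> scorer.

This mirrors the full study design on synthetic data: generate a cohort
of phantom head volumes with bimodal artifact severities, cut each into
axial slices, have a heterogeneous simulated crowd rate the slices, build
an expert gold standard at the volume level, weight the raters against
it, amplify labels to every slice, and finally train the image-based
scorer on the amplified labels, evaluating it on a held-out
subject-grouped test split against the generator's true labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import (
    amplify_labels,
    build_design_matrix,
    equal_weight_scores,
    fit_weighted_aggregator,
)
from .crowdsim import (
    ActivityPrior,
    ReliabilityPrior,
    filter_raters,
    sample_rater_pool,
    simulate_ratings,
)
from .gold_standard import build_gold_standard, simulate_expert_panel
from .metrics import auc_mann_whitney
from .phantom import (
    HeadConfig,
    QualitySpec,
    apply_motion_artifact,
    generate_phantom_volume,
    sample_severities,
)
from .qc_cnn import (
    MultiSeedResult,
    RandomConvBackbone,
    evaluate_multi_seed,
    extract_features,
    split_grouped,
)
from .slice_prep import pad_slice, select_slices

__all__ = ["simulate_slice_cohort", "run_end_to_end", "EndToEndResult"]


def simulate_slice_cohort(
    n_subjects: int = 48,
    fail_fraction: float = 0.35,
    shape: tuple[int, int, int] = (128, 128, 220),
    noise_sd: float = 0.03,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Phantom cohort cut into rated-ready padded slices.

    Each subject gets a slightly jittered head geometry, a severity drawn
    from the bimodal mixture, and per-slice motion corruption at that
    severity. Returns the manifest (subject_id, slice_id, slice_index,
    severity, q, true_label) and the padded slice images keyed by
    slice_id.
    """
    rng = np.random.default_rng(seed)
    severities = sample_severities(n_subjects, fail_fraction=fail_fraction, seed=seed)
    rows, images = [], {}
    for i in range(n_subjects):
        subject = f"sub-{i:04d}"
        jitter = rng.uniform(-0.02, 0.02)
        cfg = HeadConfig(semi_axis_frac=(0.97 + jitter, 0.97 - jitter))
        vol = generate_phantom_volume(
            shape=shape,
            structure_params=cfg,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
            subject_id=subject,
        )
        spec = QualitySpec(severity=float(severities[i]))
        for idx in select_slices(vol):
            img = vol.axial_slice(idx)
            if spec.severity > 0:
                img = apply_motion_artifact(
                    img, spec.severity, seed=int(rng.integers(2**31))
                )
            sid = f"{subject}_s{idx:03d}"
            images[sid] = pad_slice(img)
            rows.append(
                {
                    "subject_id": subject,
                    "slice_id": sid,
                    "slice_index": idx,
                    "severity": spec.severity,
                    "q": spec.q,
                    "true_label": spec.true_label,
                }
            )
    return pd.DataFrame(rows), images


@dataclass
class EndToEndResult:
    manifest: pd.DataFrame
    amplified: pd.Series  # slice_id -> weighted aggregator score
    equal_weight: pd.Series
    weighted_test_auc: float  # aggregator vs gold on held-out gold slices
    equal_weight_test_auc: float
    scorer_eval: MultiSeedResult
    n_gold_slices: int
    retained_raters: list[str]


def run_end_to_end(
    n_subjects: int = 48,
    n_raters: int = 65,
    mean_ratings_per_slice: float = 22.0,
    unreliable_fraction: float = 0.0,
    gold_fraction: float = 0.5,
    n_estimators: int = 200,
    cv_folds: int = 5,
    scorer_seeds: int = 3,
    eval_severity_margin: float = 0.15,
    seed: int = 0,
) -> EndToEndResult:
    """Run the whole synthetic study once.

    ``gold_fraction`` of subjects are put before the expert panel; the
    confidently, unanimously rated ones become the gold standard whose
    slice-level labels supervise the rater weighting. The scorer is
    trained as a regression on every slice (including ambiguous ones)
    but evaluated, as a classifier, against the true labels of
    *confidently labeled* test slices only — those whose severity lies
    at least ``eval_severity_margin`` away from the 0.5 label boundary,
    the synthetic analogue of binarizing only confident gold ratings.
    """
    manifest, images = simulate_slice_cohort(n_subjects=n_subjects, seed=seed)

    # crowd ratings over all slices
    pool = sample_rater_pool(
        n_raters,
        reliability_prior=ReliabilityPrior(unreliable_fraction=unreliable_fraction),
        activity_prior=ActivityPrior(),
        seed=seed + 1,
    )
    n_events = int(mean_ratings_per_slice * len(manifest))
    events = simulate_ratings(
        pool, manifest[["slice_id", "q"]], n_events=n_events, seed=seed + 2
    )

    # expert gold standard at the volume level, inherited by slices
    rng = np.random.default_rng(seed + 3)
    subjects = manifest["subject_id"].unique()
    n_gold_subj = max(4, int(round(gold_fraction * len(subjects))))
    gold_subjects = rng.choice(subjects, size=n_gold_subj, replace=False)
    subj_truth = manifest.drop_duplicates("subject_id").set_index("subject_id")[
        "true_label"
    ]
    panel = simulate_expert_panel(
        gold_subjects, subj_truth.loc[gold_subjects], seed=seed + 4
    )
    gold = build_gold_standard(panel)
    gold_map = gold.labels.set_index("image_id")["label"]
    gold_slices = manifest[manifest["subject_id"].isin(gold_map.index)].copy()
    gold_slices["label"] = gold_slices["subject_id"].map(gold_map)

    # rater filtering and weighting
    retained = filter_raters(events, set(gold_slices["slice_id"]))
    design = build_design_matrix(events, raters=retained)
    eq_scores = equal_weight_scores(events, raters=retained)

    gold_ids = [s for s in gold_slices["slice_id"] if s in design.index]
    gold_labels = gold_slices.set_index("slice_id").loc[gold_ids, "label"]
    from .aggregation import split_gold

    x_tr, y_tr, x_te, y_te = split_gold(
        design.loc[gold_ids], gold_labels, seed=seed + 5
    )
    fit = fit_weighted_aggregator(
        x_tr, y_tr, n_estimators=n_estimators, cv_folds=cv_folds, seed=seed + 6
    )
    weighted_auc = auc_mann_whitney(fit.predict_scores(x_te), y_te)
    equal_auc = auc_mann_whitney(eq_scores.loc[x_te.index], y_te)

    amplified = fit.predict_scores(design)

    # image scorer on amplified labels
    backbone = RandomConvBackbone(seed=seed + 7)
    features = extract_features(images, backbone=backbone)
    confident = manifest[
        (manifest["severity"] - 0.5).abs() >= eval_severity_margin
    ]
    eval_truth = confident.set_index("slice_id")["true_label"]
    # grouped split; re-draw (deterministically) until the test partition
    # carries both classes of confident slices so the evaluation AUC is
    # defined
    for k in range(50):
        split = split_grouped(manifest, seed=seed + 8 + k)
        test_truth = eval_truth.reindex(split.ids("test")).dropna()
        if test_truth.nunique() == 2:
            break
    else:
        raise RuntimeError("could not find a test split with both classes")
    scorer_eval = evaluate_multi_seed(
        features,
        amplified.reindex(features.index)
        .fillna(eq_scores.reindex(features.index))
        .fillna(0.5),
        split,
        gold_labels=eval_truth,
        n_seeds=scorer_seeds,
        base_seed=seed + 9,
    )
    return EndToEndResult(
        manifest=manifest,
        amplified=amplified,
        equal_weight=eq_scores,
        weighted_test_auc=float(weighted_auc),
        equal_weight_test_auc=float(equal_auc),
        scorer_eval=scorer_eval,
        n_gold_slices=len(gold_ids),
        retained_raters=retained,
    )
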