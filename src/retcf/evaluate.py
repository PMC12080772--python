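"""Pipeline-level evaluation of counterfactual batches.

Mirrors the quantitative procedures used to assess guided-diffusion
counterfactuals: the study selection filter (original correctly classified
and target confidence above 0.5 on the generated image), the flip-rate
sweep over the distance-regularization strength lambda_d, and lesion-count
deltas measured by the phantom lesion oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import lesion_oracle


@dataclass
class FilterReport:
    kept: list            # indices into the input pairs
    excluded: list
    n_misclassified_original: int
    n_low_confidence: int


def filter_counterfactuals(pairs, classifier, threshold: float = 0.5) -> FilterReport:
    """Keep (original, result) pairs whose original is correctly classified
    and whose counterfactual reaches target confidence strictly above the
    threshold.

    ``pairs`` is a sequence of (original_pixels, true_label, result).
    """
    kept, excluded = [], []
    n_mis = n_low = 0
    for i, (x0, label, res) in enumerate(pairs):
        pred = int(np.argmax(classifier.predict_proba(np.asarray(x0)[None])[0]))
        if pred != int(label):
            n_mis += 1
            excluded.append(i)
            continue
        if not res.target_confidence > threshold:
            n_low += 1
            excluded.append(i)
            continue
        kept.append(i)
    return FilterReport(kept=kept, excluded=excluded,
                        n_misclassified_original=n_mis, n_low_confidence=n_low)


def flip_rate_table(results_by_lambda: dict) -> pd.DataFrame:
    """Non-flip fractions per lambda_d and direction.

    ``results_by_lambda`` maps lambda_d -> {direction: list[CounterfactualResult]}
    with directions "healthy_to_diseased" / "diseased_to_healthy"; only
    counterfactuals of correctly-classified originals should be passed in
    (the denominator of the reported fraction).
    Rows are sorted by lambda_d descending.
    """
    rows = []
    for lam in sorted(results_by_lambda, reverse=True):
        row = {"lambda_d": lam}
        for direction, results in results_by_lambda[lam].items():
            if len(results) == 0:
                row[direction] = np.nan
                continue
            row[direction] = float(np.mean([not r.flipped for r in results]))
            row[f"n_{direction}"] = len(results)
        rows.append(row)
    return pd.DataFrame(rows)


def lesion_delta_report(pairs, modality: str = "fundus") -> dict:
    """Median per-type lesion-count change (counterfactual - original).

    ``pairs`` is a sequence of (original_pixels, counterfactual_pixels).
    """
    deltas: dict[str, list] = {}
    totals = []
    for x0, xcf in pairs:
        c0 = lesion_oracle(np.asarray(x0), modality)
        c1 = lesion_oracle(np.asarray(xcf), modality)
        for t in c0:
            deltas.setdefault(t, []).append(c1[t] - c0[t])
        totals.append(sum(c1.values()) - sum(c0.values()))
    out = {t: float(np.median(v)) for t, v in deltas.items()}
    out["total"] = float(np.median(totals))
    return out
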