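"""AICc ranking and full (zero-substitution) multimodel averaging.

Shared by the historic mixed models and the change GLS. Candidate fits need
``aicc``, ``converged``, ``loglik``, ``k``, ``terms`` and per-term ``beta``
/ ``se_beta`` dicts. Averaging runs over the converged fits within
``delta_max`` AICc of the best; a term absent from a model contributes an
estimate of 0 with SE 0 (full averaging), and the unconditional SE folds in
between-model spread: SE = sum_i w_i sqrt(se_i^2 + (b_i - b_avg)^2).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

Z95 = 1.959963984540054


def akaike_table(fits: list) -> tuple[pd.DataFrame, list, np.ndarray]:
    """Rank converged fits by AICc; returns (table, kept fits, weights)."""
    ok = [f for f in fits if f.converged]
    if len(ok) < len(fits):
        warnings.warn(f"excluding {len(fits) - len(ok)} non-converged fit(s) "
                      "from model selection")
    if not ok:
        raise ValueError("no converged fits to select among")
    aiccs = np.array([f.aicc for f in ok])
    delta = aiccs - aiccs.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()
    table = pd.DataFrame({
        "terms": ["+".join(f.terms) or "1" for f in ok],
        "loglik": [f.loglik for f in ok],
        "k": [f.k for f in ok],
        "aicc": aiccs,
        "delta_aicc": delta,
        "weight": w,
    }).sort_values("aicc", ignore_index=True)
    return table, ok, w


def full_average(fits: list, term_universe: tuple[str, ...],
                 delta_max: float = 2.0, z: float = Z95
                 ) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """(model table, averaged-coefficient table, support term sets)."""
    table, ok, w = akaike_table(fits)
    delta = np.array([f.aicc for f in ok]) - min(f.aicc for f in ok)
    support = [i for i in range(len(ok)) if delta[i] <= delta_max]
    ws = w[support] / w[support].sum()
    terms = ["intercept"] + [t for t in term_universe
                             if any(t in f.terms for f in ok)]
    rows = []
    for term in terms:
        b = np.array([ok[i].beta.get(term, 0.0) for i in support])
        se_c = np.array([ok[i].se_beta.get(term, 0.0) for i in support])
        b_avg = float(ws @ b)
        se_avg = float(ws @ np.sqrt(se_c**2 + (b - b_avg) ** 2))
        lo, hi = b_avg - z * se_avg, b_avg + z * se_avg
        rows.append({"term": term, "estimate": b_avg, "se": se_avg,
                     "ci_lo": lo, "ci_hi": hi,
                     "significant": bool(lo > 0 or hi < 0)})
    averaged = pd.DataFrame(rows)
    return table, averaged, [ok[i].terms for i in support]
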