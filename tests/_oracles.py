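"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is a deliberately plain, loop-based restatement of the
published procedure, sharing no code with the package internals.
"""

import math


def column_pipeline_oracle(column, pitch=0.024445, window=5, threshold=45.0,
                           discard_high=11.0):
    """Literal per-column pipeline, executed step by step with plain loops.

    Extract the column -> sort pixel values -> select the fourth-largest
    value -> slide a five-pixel window down from the start -> at the
    first window whose mean is < 45, compute the attenuation coefficient
    (ending row = window centre, ending gray = window mean) -> apply the
    discard rules. Returns ``(mu_or_None, status_string)``.
    """
    vals = [float(v) for v in column]
    p_start = sorted(vals, reverse=True)[3]
    row_start = vals.index(p_start)
    if p_start <= threshold:
        return None, "no_segment"
    r = row_start + 1
    while r + window <= len(vals):
        m = sum(vals[r:r + window]) / window
        if m < threshold:
            if m <= 0:
                return None, "no_segment"
            row_end = r + window // 2
            L = (row_end - row_start) * pitch
            mu = 10.0 * math.log10(p_start / m) / L
            if mu > discard_high:
                return mu, "discarded_high"
            if mu < 0:
                return mu, "discarded_negative"
            return mu, "accepted"
        r += 1
    return None, "no_segment"


def auc_pair_oracle(tumor, nontumor, lower_is_tumor=True):
    """Exhaustive Mann-Whitney pair count, ties counted one half."""
    score = 0.0
    for t in tumor:
        for n in nontumor:
            on_tumor_side = t < n if lower_is_tumor else t > n
            if on_tumor_side:
                score += 1.0
            elif t == n:
                score += 0.5
    return score / (len(tumor) * len(nontumor))


def grid_count_oracle(image, top, left, width, height, lo, hi):
    """Double-loop band count over an ROI."""
    n = 0
    for r in range(top, top + height):
        for c in range(left, left + width):
            if lo <= image[r][c] <= hi:
                n += 1
    return n


def welch_oracle(a, b):
    """Textbook Welch statistic with Satterthwaite df; no p-value."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
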