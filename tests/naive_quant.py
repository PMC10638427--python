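"""Independent, deliberately naive transcription of the quantitative
strategy, coded straight from its ten numbered steps over plain dicts.

Used only as an oracle: nothing here imports the implementation under
test. Pure-Python loops and ``math`` throughout.
"""

import math


def naive_quantitative(
    raw,
    protein_order,
    exp_runs,
    c1_runs,
    c2_runs,
    cond_runs,
    fold_threshold_log2=1.5,
    alpha_adjusted=0.01,
    sd_mode="sample",
    zscore_scale="raw",
):
    """raw: {run_code: {accession: raw_intensity}}.

    Returns {accession: record dict} for proteins detected in >=1
    experimental replicate.
    """
    # steps 1-2: median normalization (0 -> 1) then log10
    trans = {}
    for run in cond_runs:
        nonzero = sorted(v for v in (raw[run][a] for a in protein_order) if v > 0)
        if nonzero:
            k = len(nonzero)
            if k % 2:
                med = nonzero[k // 2]
            else:
                med = (nonzero[k // 2 - 1] + nonzero[k // 2]) / 2
        trans[run] = {}
        for a in protein_order:
            v = raw[run][a]
            trans[run][a] = math.log10(v / med) if v > 0 else 0.0

    # step 3: global variance / SD over every transformed value
    pool = []
    for run in cond_runs:
        for a in protein_order:
            pool.append(trans[run][a])
    n = len(pool)
    total = 0.0
    for v in pool:
        total += v
    mean = total / n
    ss = 0.0
    for v in pool:
        ss += (v - mean) ** 2
    var = ss / (n - 1) if sd_mode == "sample" else ss / n
    sd = math.sqrt(var)

    log10_2 = math.log10(2.0)
    scale = 1.0 if zscore_scale == "raw" else math.sqrt(2.0 / 3.0)

    def judge(av_exp, av_ctrl):
        # steps 5-7 (and 8): absence rule, fold filter, one-way z
        if av_ctrl == 0:
            return "absent_in_control", math.nan, math.nan, math.nan
        diff = av_exp - av_ctrl
        log2fc = diff / log10_2
        if not log2fc >= fold_threshold_log2:
            return "rejected", log2fc, math.nan, math.nan
        denom = sd * scale
        if denom == 0:
            return "enriched", log2fc, math.inf, 0.0
        z = diff / denom
        p = math.erfc(z / math.sqrt(2.0)) / 2
        return "enriched", log2fc, z, p

    records = {}
    for a in protein_order:
        if not any(raw[r][a] > 0 for r in exp_runs):
            continue
        # step 4: triplicate averages
        av_exp = (trans[exp_runs[0]][a] + trans[exp_runs[1]][a] + trans[exp_runs[2]][a]) / 3
        av_c1 = (trans[c1_runs[0]][a] + trans[c1_runs[1]][a] + trans[c1_runs[2]][a]) / 3
        av_c2 = (trans[c2_runs[0]][a] + trans[c2_runs[1]][a] + trans[c2_runs[2]][a]) / 3
        v1, fc1, z1, p1 = judge(av_exp, av_c1)
        v2, fc2, z2, p2 = judge(av_exp, av_c2)
        records[a] = {
            "av_exp": av_exp, "av_c1": av_c1, "av_c2": av_c2,
            "verdict_c1": v1, "verdict_c2": v2,
            "log2fc_c1": fc1, "log2fc_c2": fc2,
            "z_c1": z1, "z_c2": z2, "p_c1": p1, "p_c2": p2,
            "padj_c1": math.nan, "padj_c2": math.nan,
            # step 9: present in all three experimental replicates
            "present_all_reps": all(raw[r][a] > 0 for r in exp_runs),
        }

    # step 7 multiplicity adjustment, per control family of tested proteins
    for key in ("c1", "c2"):
        tested = [a for a in protein_order
                  if a in records and records[a][f"verdict_{key}"] == "enriched"]
        adj = naive_bh([records[a][f"p_{key}"] for a in tested])
        for a, q in zip(tested, adj):
            records[a][f"padj_{key}"] = q

    # step 10: final call
    for a, r in records.items():
        ok = []
        for key in ("c1", "c2"):
            v = r[f"verdict_{key}"]
            ok.append(v == "absent_in_control"
                      or (v == "enriched" and r[f"padj_{key}"] <= alpha_adjusted))
        r["final_hit"] = bool(r["present_all_reps"] and ok[0] and ok[1])
    return records


def naive_bh(pvalues):
    """Hand-coded Benjamini-Hochberg step-up, input order preserved."""
    m = len(pvalues)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: pvalues[i])  # stable
    adjusted_sorted = [math.nan] * m
    running = math.inf
    for pos in range(m - 1, -1, -1):
        term = (pvalues[order[pos]] * m) / (pos + 1)
        if term < running:
            running = term
        adjusted_sorted[pos] = min(running, 1.0)
    out = [math.nan] * m
    for pos, i in enumerate(order):
        out[i] = adjusted_sorted[pos]
    return out
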