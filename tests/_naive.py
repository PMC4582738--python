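"""Independent brute-force oracles used by the test suite.

Everything here is written as a direct, quadratic transliteration of the
analysis rules, independent of the production implementations it checks.
"""

from __future__ import annotations


def naive_call_domains(records, params):
    """Domain calling written as literally as possible.

    ``records`` is a list of ``(pos, n_meth, n_unmeth)`` tuples for one
    chromosome; returns ``[(start, end, cls), ...]`` after refinement.
    """
    from fractions import Fraction

    covered = [(p, m, u) for p, m, u in records if m + u >= 1]
    win, step = params.window_n_cpgs, params.step_n_cpgs
    windows = []
    i = 0
    while i + win <= len(covered):
        members = covered[i : i + win]
        # exact rational arithmetic: the oracle never suffers float rounding
        scored = [
            Fraction(100 * m, m + u)
            for p, m, u in members
            if m + u >= params.min_reads_per_cpg
        ]
        meth = (
            sum(scored) / len(scored)
            if len(scored) >= params.min_scored_cpgs
            else None
        )
        windows.append((members[0][0], members[-1][0] + 1, meth))
        i += step

    def seeds(cls):
        out = []
        for s, e, meth in windows:
            if meth is None:
                continue
            if cls == "hyper" and meth > params.hyper_cut:
                out.append([s, e])
            if cls == "hypo" and meth < params.hypo_cut:
                out.append([s, e])
        # merge overlapping or bookended, repeatedly
        changed = True
        while changed:
            changed = False
            out.sort()
            for i in range(len(out) - 1):
                if out[i + 1][0] <= out[i][1]:
                    out[i][1] = max(out[i][1], out[i + 1][1])
                    del out[i + 1]
                    changed = True
                    break
        return out

    runs = [[s, e, "hyper"] for s, e in seeds("hyper")] + [
        [s, e, "hypo"] for s, e in seeds("hypo")
    ]
    runs.sort()
    # resolve opposite-class overlaps at the midpoint of the shared span,
    # looping until no overlap remains; containment leaves a surviving tail
    changed = True
    while changed:
        changed = False
        runs.sort()
        for i in range(len(runs) - 1):
            a, b = runs[i], runs[i + 1]
            if b[0] < a[1]:
                shared_s, shared_e = b[0], min(a[1], b[1])
                mid = (shared_s + shared_e) // 2
                if a[1] > b[1]:
                    runs.append([b[1], a[1], a[2]])
                a[1] = mid
                b[0] = mid
                runs[:] = [r for r in runs if r[0] < r[1]]
                changed = True
                break
    runs.sort()

    # refinement: merge gaps, absorb small opposite, drop small, merge gaps
    def merge_gaps(doms):
        changed = True
        while changed:
            changed = False
            for i in range(len(doms) - 1):
                if (
                    doms[i][2] == doms[i + 1][2]
                    and doms[i + 1][0] - doms[i][1] < params.merge_gap
                ):
                    doms[i][1] = max(doms[i][1], doms[i + 1][1])
                    del doms[i + 1]
                    changed = True
                    break
        return doms

    doms = merge_gaps([list(r) for r in runs])
    changed = True
    while changed:
        changed = False
        for i in range(1, len(doms) - 1):
            if (
                doms[i][1] - doms[i][0] < params.opposite_absorb_max
                and doms[i - 1][2] == doms[i + 1][2]
                and doms[i][2] != doms[i - 1][2]
            ):
                doms[i - 1][1] = doms[i + 1][1]
                del doms[i : i + 2]
                changed = True
                break
    doms = [d for d in doms if d[1] - d[0] >= params.min_domain_len]
    doms = merge_gaps(doms)
    return [(s, e, c) for s, e, c in doms]


def naive_overlap_fraction(start, end, intervals):
    """Base-by-base overlap fraction for small instances."""
    covered = 0
    for x in range(start, end):
        if any(s <= x < e for s, e in intervals):
            covered += 1
    return covered / (end - start)


def naive_cdf_gap_threshold(tx_values, ig_values):
    """Brute-force CDF-gap argmax over the pooled grid."""
    grid = sorted(set(list(tx_values) + list(ig_values)))
    best_t, best_gap = None, -2.0
    for t in grid:
        f_tx = sum(v <= t for v in tx_values) / len(tx_values)
        f_ig = sum(v <= t for v in ig_values) / len(ig_values)
        gap = f_ig - f_tx
        if gap > best_gap:
            best_gap, best_t = gap, t
    return best_t, best_gap


def naive_classify(t, refs):
    """Pairwise transcript classification over all reference transcripts."""

    def exonic_overlap(a_exons, b_exons):
        total = 0
        for s1, e1 in a_exons:
            for s2, e2 in b_exons:
                total += max(0, min(e1, e2) - max(s1, s2))
        return total

    def introns(exons):
        return [
            (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
        ]

    rank = {"=": 0, "c": 1, "j": 2, "o": 3, "i": 4, "x": 5, "u": 6}
    best = "u"
    for r in refs:
        if r.chrom != t.chrom:
            continue
        codes = []
        t_in, r_in = introns(t.exons), introns(r.exons)
        ov = exonic_overlap(t.exons, r.exons)
        if t.strand == r.strand:
            if (t_in and t_in == r_in) or (
                not t_in and not r_in and t.exons == r.exons
            ):
                codes.append("=")
            if ov > 0 and t.exons[0][0] >= r.exons[0][0] and t.exons[-1][1] <= r.exons[-1][1]:
                if not t_in:
                    if any(
                        t.exons[0][0] >= s and t.exons[-1][1] <= e
                        for s, e in r.exons
                    ):
                        codes.append("c")
                else:
                    n = len(t_in)
                    if any(
                        r_in[i : i + n] == t_in for i in range(len(r_in) - n + 1)
                    ):
                        codes.append("c")
            if t_in and set(t_in) & set(r_in):
                codes.append("j")
            if ov > 0:
                codes.append("o")
        for s, e in r_in:
            if t.exons[0][0] >= s and t.exons[-1][1] <= e:
                codes.append("i")
        if t.strand != r.strand and ov > 0:
            codes.append("x")
        for code in codes:
            if rank[code] < rank[best]:
                best = code
    return best
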