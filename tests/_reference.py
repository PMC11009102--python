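"""Independent reference implementations used as test oracles.

These are literal, loop-based transcriptions of the scan definitions,
kept deliberately separate from the package implementation.
"""


def reference_roh(pos, geno, params):
    """Direct ROH scan: windows, hit rates, eligibility, run constraints."""
    n = len(pos)
    w = params.window_snps
    if n == 0:
        return []
    is_het = [g == 1 for g in geno]
    is_mis = [g == -1 for g in geno]
    if n < w:
        window_starts = [0]
        w_eff = n
    else:
        window_starts = list(range(n - w + 1))
        w_eff = w
    passing = []
    for s in window_starts:
        het = sum(is_het[s : s + w_eff])
        mis = sum(is_mis[s : s + w_eff])
        passing.append(het <= params.max_het and mis <= params.max_missing)
    eligible = []
    for i in range(n):
        hits = 0
        cover = 0
        # window starting at s covers SNP i iff s <= i <= s + w_eff - 1
        for s in range(max(0, i - w_eff + 1), min(len(window_starts) - 1, i) + 1):
            cover += 1
            if passing[s]:
                hits += 1
        eligible.append(hits / cover >= params.hit_threshold)
    segments = []
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1]:
            j += 1
        starts = [i]
        for k in range(i, j):
            if pos[k + 1] - pos[k] > params.max_gap_kb * 1000:
                starts.append(k + 1)
        bounds = starts + [j + 1]
        for a, b in zip(bounds[:-1], bounds[1:]):
            n_snp = b - a
            length = pos[b - 1] - pos[a] + 1
            if (
                n_snp >= params.min_snps
                and length >= params.min_length_kb * 1000
                and length / n_snp <= params.max_density_kb_per_snp * 1000
            ):
                segments.append((int(pos[a]), int(pos[b - 1]), n_snp))
        i = j + 1
    return segments
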