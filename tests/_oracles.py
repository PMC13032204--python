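"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit loops and textbook formulas, on
purpose: these functions are the oracles the vectorised package code is
checked against, so they must not share any code path with it.
"""

from __future__ import annotations

import math


def dice_bruteforce(a, b) -> float:
    """2|A∩B|/(|A|+|B|) by pixel-wise iteration over two boolean rasters."""
    inter = na = nb = 0
    rows, cols = len(a), len(a[0])
    for i in range(rows):
        for j in range(cols):
            if a[i][j]:
                na += 1
            if b[i][j]:
                nb += 1
            if a[i][j] and b[i][j]:
                inter += 1
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def pearson_bruteforce(x, y) -> float:
    """Sample correlation from the raw covariance formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    sxx = sum((x[i] - mx) ** 2 for i in range(n))
    syy = sum((y[i] - my) ** 2 for i in range(n))
    return sxy / math.sqrt(sxx * syy)


def bland_altman_bruteforce(a, b, mult: float = 1.96):
    """(bias, sd_diff, loa_lower, loa_upper) with sample (n−1) SD."""
    n = len(a)
    d = [a[i] - b[i] for i in range(n)]
    bias = sum(d) / n
    var = sum((di - bias) ** 2 for di in d) / (n - 1)
    sd = math.sqrt(var)
    return bias, sd, bias - mult * sd, bias + mult * sd


def icc_a1_bruteforce(table) -> float:
    """Two-way absolute-agreement single-measures ICC from explicit ANOVA sums.

    table: list of n rows, each a list of k rater values.
    """
    n = len(table)
    k = len(table[0])
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def label_components_bruteforce(mask, connectivity: int = 8):
    """Connected components by iterative flood fill; returns list of pixel sets."""
    rows, cols = len(mask), len(mask[0])
    if connectivity == 4:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = [[False] * cols for _ in range(rows)]
    comps = []
    for i in range(rows):
        for j in range(cols):
            if mask[i][j] and not seen[i][j]:
                stack = [(i, j)]
                seen[i][j] = True
                comp = set()
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr, dc in offs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < rows and 0 <= cc < cols and mask[rr][cc] and not seen[rr][cc]:
                            seen[rr][cc] = True
                            stack.append((rr, cc))
                comps.append(comp)
    return comps
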