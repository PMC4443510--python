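"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written with plain Python loops and dictionaries, from the
documented rules, with no imports from the modules they check.
"""

from __future__ import annotations

import math

NUCS = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# trait-linked SNP filter

def brute_call(depths: dict[str, int], min_frac: float, absent_max: int = 0):
    """(state, allele, depth) for one aggregated entity."""
    total = sum(depths.get(n, 0) for n in NUCS)
    if total <= absent_max:
        return ("absent", None, total)
    best = max(NUCS, key=lambda n: depths.get(n, 0))
    if depths.get(best, 0) / total >= min_frac:
        return ("homozygous", best, total)
    return ("ambiguous", None, total)


def brute_filter_site(rows, donor="Yitpi", min_frac=0.95, min_conc=4,
                      min_depth=2, mode="joint"):
    """Evaluate one site from raw depth rows (list of dicts with entity,
    pool, timepoint, A, C, G, T). Returns dict of criterion flags."""
    agg: dict[tuple[str, str], dict[str, int]] = {}
    for row in rows:
        key = (row["entity"], row["pool"])
        acc = agg.setdefault(key, {n: 0 for n in NUCS})
        for n in NUCS:
            acc[n] += int(row[n])
    calls = {key: brute_call(d, min_frac) for key, d in agg.items()}
    founders = sorted({e for (e, p) in agg if p == "."})
    families = sorted({e for (e, p) in agg if p in ("A", "B")})

    donor_state, donor_hom_allele, _ = calls[(donor, ".")]

    def majority(keys):
        votes: dict[str, int] = {}
        for k in keys:
            st, al, _ = calls[k]
            if st == "homozygous":
                votes[al] = votes.get(al, 0) + 1
        if not votes:
            return None
        best_n = max(votes.values())
        return sorted(a for a, v in votes.items() if v == best_n)[0]

    if donor_state == "homozygous":
        donor_allele = donor_hom_allele
    else:
        donor_allele = majority([(f, "A") for f in families])

    c1 = donor_allele is not None
    for f in founders:
        if f == donor:
            continue
        st, al, _ = calls[(f, ".")]
        if st == "homozygous" and al == donor_allele:
            c1 = False
    c2 = donor_state in ("homozygous", "absent")

    def a_ok(f):
        st, al, _ = calls[(f, "A")]
        return donor_allele is not None and st == "homozygous" and al == donor_allele

    def b_ok(f):
        st, al, _ = calls[(f, "B")]
        return donor_allele is not None and st == "homozygous" and al != donor_allele

    if mode == "joint":
        n_conc = sum(1 for f in families if a_ok(f) and b_ok(f))
        c3 = n_conc >= min_conc
    else:
        na = sum(1 for f in families if a_ok(f))
        nb = sum(1 for f in families if b_ok(f))
        n_conc = min(na, nb)
        c3 = na >= min_conc and nb >= min_conc

    support = 0
    if donor_allele is not None:
        for key, d in agg.items():
            st, al, _ = calls[key]
            if st == "homozygous" and al == donor_allele:
                support += d[donor_allele]
    c4 = donor_allele is not None and support >= min_depth

    return {
        "c1": c1, "c2": c2, "c3": c3, "c4": c4,
        "n_conc": n_conc, "donor_allele": donor_allele,
        "passed": c1 and c2 and c3 and c4,
    }


# ---------------------------------------------------------------------------
# TMM normalization

def brute_tmm(columns: list[list[float]], trim_m=0.30, trim_a=0.05):
    """Normalization factors for a list of count columns (genes nested)."""
    n_samples = len(columns)
    libs = [sum(col) for col in columns]
    q75 = []
    for col, lib in zip(columns, libs):
        vals = sorted(x / lib for x in col)
        q75.append(_quantile(vals, 0.75))
    mean_q = sum(q75) / n_samples
    ref = min(range(n_samples), key=lambda j: abs(q75[j] - mean_q))

    factors = []
    for j in range(n_samples):
        factors.append(
            _brute_pair(columns[j], columns[ref], libs[j], libs[ref], trim_m, trim_a)
        )
    log_mean = sum(math.log(f) for f in factors) / n_samples
    return [f / math.exp(log_mean) for f in factors]


def _quantile(sorted_vals, q):
    # linear interpolation, matching numpy's default
    n = len(sorted_vals)
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def _rank(values):
    """Average ranks (1-based), ties averaged."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _brute_pair(obs, ref, lib_o, lib_r, trim_m, trim_a):
    ms, as_, ws = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            po, pr = o / lib_o, r / lib_r
            ms.append(math.log2(po / pr))
            as_.append(0.5 * math.log2(po * pr))
            ws.append((lib_o - o) / (lib_o * o) + (lib_r - r) / (lib_r * r))
    if not ms:
        return 1.0
    if max(abs(m) for m in ms) < 1e-6:
        return 1.0
    n = len(ms)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = _rank(ms), _rank(as_)
    num = den = 0.0
    for i in range(n):
        if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
            num += ws[i] * ms[i]
            den += ws[i]
    if den <= 0:
        return 1.0
    return 2.0 ** (num / den)


# ---------------------------------------------------------------------------
# interval overlap

def brute_overlap(chrom_a, start_a, end_a, chrom_b, start_b, end_b):
    """Base-by-base overlap check on half-open intervals."""
    if chrom_a != chrom_b:
        return False
    bases_a = set(range(start_a, end_a))
    return any(b in bases_a for b in range(start_b, end_b))
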