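"""Venn overlaps of DEG sets, Fisher exact overlap significance, and the
key-lncRNA recurrence screen over a scheme of contrast pairings.

The two-sided Fisher p uses the point-probability rule (sum of all table
probabilities not exceeding the observed table's). Probabilities are handled
as exact integer hypergeometric numerators over a common denominator, so the
inclusion decision is exact and the only floating-point step is the final
division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

#: the four contrast pairings of the key-lncRNA screen, with the phenotype
#: label attributed to each pairing
DEFAULT_PAIRING_SCHEME = [
    ("PPROM_vs_TL", "PROM_vs_TL", "term-PROM"),
    ("PPROM_vs_PTB", "PROM_vs_PTB", "preterm-PROM"),
    ("PTB_vs_TL", "PTB_vs_PROM", "PTB"),
    ("PPROM_vs_PROM", "PPROM_vs_TL", "PROM"),
]


@dataclass(frozen=True)
class VennResult:
    a_only: int
    b_only: int
    both: int
    a_only_members: tuple[str, ...]
    b_only_members: tuple[str, ...]
    both_members: tuple[str, ...]


def venn(set_a, set_b) -> VennResult:
    """Exact two-set partition with sorted member lists."""
    a, b = set(set_a), set(set_b)
    both = a & b
    return VennResult(
        a_only=len(a - b),
        b_only=len(b - a),
        both=len(both),
        a_only_members=tuple(sorted(a - b)),
        b_only_members=tuple(sorted(b - a)),
        both_members=tuple(sorted(both)),
    )


@lru_cache(maxsize=100_000)
def _hypergeom_numerators(n_total: int, n_marked: int, n_draws: int) -> tuple[int, ...]:
    """Exact numerators C(K,k)*C(N-K,n-k) for k over the full support.

    P(X = k) = numerator_k / C(N, n); index 0 corresponds to
    k = max(0, n_draws + n_marked - n_total).
    """
    k_min = max(0, n_draws + n_marked - n_total)
    k_max = min(n_draws, n_marked)
    return tuple(
        math.comb(n_marked, k) * math.comb(n_total - n_marked, n_draws - k)
        for k in range(k_min, k_max + 1)
    )


def fisher_overlap(
    overlap_size: int, size_a: int, size_b: int, universe_size: int,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Fisher exact test of the 2x2 overlap table; returns (odds_ratio, p).

    Table: [[k, a-k], [b-k, N-a-b+k]]. The two-sided p sums every
    hypergeometric outcome whose exact probability is <= that of the
    observed table; "greater" gives the upper-tail (hypergeometric survival)
    p. The odds ratio is the sample cross-product ratio (inf when a zero
    cell forces it).
    """
    k, a, b, n_universe = overlap_size, size_a, size_b, universe_size
    if not (0 <= k <= min(a, b)):
        raise ValueError(f"need 0 <= overlap ({k}) <= min(|A|, |B|) = {min(a, b)}")
    if a + b - k > n_universe:
        raise ValueError("universe too small for the given sets")

    d = n_universe - a - b + k
    num = k * d
    den = (a - k) * (b - k)
    if den > 0:
        odds_ratio = num / den
    else:
        odds_ratio = math.inf if num > 0 else math.nan

    numerators = _hypergeom_numerators(n_universe, a, b)
    k_min = max(0, a + b - n_universe)
    obs = numerators[k - k_min]
    denom = math.comb(n_universe, b)
    if alternative == "two-sided":
        p = sum(x for x in numerators if x <= obs) / denom
    elif alternative == "greater":
        p = sum(numerators[k - k_min:]) / denom
    elif alternative == "less":
        p = sum(numerators[: k - k_min + 1]) / denom
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return odds_ratio, min(1.0, p)


@dataclass(frozen=True)
class OverlapResult:
    contrast_a: str
    contrast_b: str
    direction: str
    size_a: int
    size_b: int
    overlap_size: int
    universe_size: int
    members: tuple[str, ...]
    odds_ratio: float
    p_value: float
    label: str = ""


def overlap_test(
    set_a, set_b, universe_size: int,
    contrast_a: str = "A", contrast_b: str = "B",
    direction: str = "", label: str = "",
    alternative: str = "two-sided",
) -> OverlapResult:
    """Venn overlap of two DEG sets plus its Fisher exact significance."""
    v = venn(set_a, set_b)
    size_a = v.a_only + v.both
    size_b = v.b_only + v.both
    odds, p = fisher_overlap(v.both, size_a, size_b, universe_size, alternative)
    return OverlapResult(
        contrast_a, contrast_b, direction, size_a, size_b, v.both,
        universe_size, v.both_members, odds, p, label,
    )


def key_lncrna_screen(
    deg_sets_by_contrast: dict[str, dict[str, set[str]]],
    universe_size: int,
    scheme: list[tuple[str, str, str]] | None = None,
) -> tuple[list[OverlapResult], pd.DataFrame]:
    """Overlap tests per pairing x direction, and recurrence-ranked candidates.

    ``deg_sets_by_contrast`` maps contrast -> {"up": ids, "down": ids}. For
    each (contrast_a, contrast_b, label) pairing in the scheme and each
    direction, the overlap members are collected with the pairing's Fisher
    p. Candidates are ranked by the number of pairings in which they recur
    (ties broken lexicographically) and annotated with the pairing labels.
    """
    if scheme is None:
        scheme = DEFAULT_PAIRING_SCHEME
    overlaps: list[OverlapResult] = []
    seen_in: dict[str, set[str]] = {}
    labels_of: dict[str, set[str]] = {}
    for contrast_a, contrast_b, label in scheme:
        for name in (contrast_a, contrast_b):
            if name not in deg_sets_by_contrast:
                raise ValueError(f"unknown contrast {name!r} in pairing scheme")
        for direction in ("up", "down"):
            res = overlap_test(
                deg_sets_by_contrast[contrast_a][direction],
                deg_sets_by_contrast[contrast_b][direction],
                universe_size,
                contrast_a, contrast_b, direction, label,
            )
            overlaps.append(res)
            pairing = f"{contrast_a}&{contrast_b}"
            for member in res.members:
                seen_in.setdefault(member, set()).add(pairing)
                labels_of.setdefault(member, set()).add(label)

    rows = [
        (lnc, len(pairings), ";".join(sorted(pairings)), ";".join(sorted(labels_of[lnc])))
        for lnc, pairings in seen_in.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    candidates = pd.DataFrame(rows, columns=["lncrna_id", "recurrence", "pairings", "labels"])
    return overlaps, candidates


def overlaps_to_frame(overlaps: list[OverlapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (o.contrast_a, o.contrast_b, o.label, o.direction, o.size_a, o.size_b,
             o.overlap_size, o.universe_size, o.odds_ratio, o.p_value,
             ",".join(o.members))
            for o in overlaps
        ],
        columns=["contrast_a", "contrast_b", "label", "direction", "size_a",
                 "size_b", "overlap", "universe", "odds_ratio", "p_value", "members"],
    )
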