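"""Motif-pathway association by Fisher's exact test.

For each (motif, pathway) pair the expressed-gene universe is partitioned
into a 2x2 table: a = genes in the pathway that are motif targets, b = in
the pathway but not targets, c = targets outside the pathway, d = neither.
The two-sided Fisher p-value (minimum-likelihood method, margins fixed) is
adjusted across all tested pairs by Benjamini-Hochberg; a pair is reported
as significantly associated when q < alpha and the overlap exceeds its
expectation under independence (enrichment, not depletion, unless asked).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)`` where the odds ratio is the sample estimate
    a*d/(b*c) (inf when b*c = 0 and a*d > 0, nan for 0/0) and p sums the
    hypergeometric probabilities of all outcomes no more likely than the
    observed one, with margins fixed.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError(f"table entries must be nonnegative integers, got {v}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if b * c == 0:
        odds = np.nan if a * d == 0 else np.inf
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def motif_pathway_scan(
    targets: dict[str, set[str]],
    sets,
    universe: set[str],
    diff_motifs: list[str] | None = None,
    sig_pathways: list[str] | None = None,
    alpha: float = 0.05,
    report_depletion: bool = False,
) -> pd.DataFrame:
    """Test every (motif, pathway) pair for target/membership association.

    ``targets`` maps motif to its gene-level target set, ``sets`` is a
    :class:`~ontarget.gsea.GeneSetCollection`, ``universe`` the expressed
    genes (the background).  ``diff_motifs`` / ``sig_pathways`` restrict the
    scan to differentially activated motifs and significantly enriched
    pathways.  Returns one row per tested pair with the 2x2 table, odds
    ratio, p, BH q and a ``significant`` flag (q < alpha and positive
    association unless ``report_depletion``).
    """
    from .diffexpr import bh_adjust

    if not universe:
        raise ValueError("empty gene universe")
    universe = set(universe)
    motifs = list(targets) if diff_motifs is None else [m for m in diff_motifs if m in targets]
    pw_names = [name for name, _ in sets]
    if sig_pathways is not None:
        pw_names = [p for p in pw_names if p in set(sig_pathways)]
    set_lookup = dict(sets)

    rows = []
    n_univ = len(universe)
    for motif in sorted(motifs):
        tg = targets[motif] & universe
        for pw in sorted(pw_names):
            members = set(set_lookup[pw]) & universe
            a = len(members & tg)
            b = len(members) - a
            c = len(tg) - a
            d = n_univ - a - b - c
            odds, p = fisher_exact_2x2(a, b, c, d)
            rows.append((motif, pw, a, b, c, d, odds, p))
    out = pd.DataFrame(rows, columns=["motif", "pathway", "a", "b", "c", "d", "odds_ratio", "p"])
    if out.empty:
        out["q"] = out["significant"] = []
        return out
    out["q"] = bh_adjust(out["p"].to_numpy())
    expected = (out.a + out.b) * (out.a + out.c) / n_univ
    enriched = out.a > expected
    out["significant"] = (out.q < alpha) & (enriched | report_depletion)
    return out.sort_values(["p", "motif", "pathway"], kind="mergesort").reset_index(drop=True)
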