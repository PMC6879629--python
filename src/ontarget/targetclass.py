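"""Step-wise classification of drug responses into on- and off-target calls.

For each entity (promoter or pathway) under one drug in one cell line, four
ternary significance signs are available: the two knockdowns of the drug's
primary target (two independent siRNAs) and the two drug timepoints (6 h and
48 h).  The filter proceeds in three steps:

1. entities with opposite signs in the two knockdowns are excluded
   (knockdown conflict);
2. entities with opposite signs at the two timepoints are excluded (time
   conflict); otherwise the drug sign is the 48 h sign when nonzero (the
   long-term effect), else the 6 h sign;
3. a nonzero drug sign matching the knockdown consensus is an on-target
   call; a nonzero drug sign with zero or opposite knockdown consensus is an
   off-target call; a zero drug sign is null (a knockdown-only change is not
   a drug response).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

LABELS = (
    "on_up",
    "on_down",
    "off_up",
    "off_down",
    "excluded_kd_conflict",
    "excluded_time_conflict",
    "null",
)


@dataclass(frozen=True)
class SignVector:
    """Ternary significance signs for one entity under one drug/cell."""

    s_kd1: int
    s_kd2: int
    s_6h: int
    s_48h: int

    def __post_init__(self):
        for v in (self.s_kd1, self.s_kd2, self.s_6h, self.s_48h):
            if v not in (-1, 0, 1):
                raise ValueError(f"signs must be ternary, got {v}")


@dataclass(frozen=True)
class TargetCall:
    entity_id: str
    drug: str
    cell_line: str
    label: str
    kd_consensus: int
    drug_sign: int


def classify(sv: SignVector, kd_both: bool = False, kd_conflict_to_off: bool = False) -> tuple[str, int, int]:
    """Classify one sign vector; returns (label, kd_consensus, drug_sign).

    ``kd_both`` demands significance in both knockdowns for an on-target
    call (strict mode); the default permissive mode only excludes outright
    conflicts.  ``kd_conflict_to_off`` routes knockdown-conflict entities to
    the off-target class instead of excluding them.
    """
    k = int(np.sign(sv.s_kd1 + sv.s_kd2))
    kd_conflict = sv.s_kd1 * sv.s_kd2 == -1
    if kd_conflict and not kd_conflict_to_off:
        return "excluded_kd_conflict", 0, 0
    if sv.s_6h * sv.s_48h == -1:
        return "excluded_time_conflict", k, 0
    d = sv.s_48h if sv.s_48h != 0 else sv.s_6h
    if d == 0:
        return "null", k, 0
    direction = "up" if d > 0 else "down"
    if kd_conflict:  # only reachable with kd_conflict_to_off
        return f"off_{direction}", 0, d
    on = (k == d) if not kd_both else (sv.s_kd1 == sv.s_kd2 == d)
    if on:
        return f"on_{direction}", k, d
    return f"off_{direction}", k, d


def classify_table(
    de: pd.DataFrame,
    contrast_map: dict[str, dict[str, str]],
    cell_line: str = "cell",
    alpha_ignored: None = None,
    kd_both: bool = False,
) -> pd.DataFrame:
    """Classify every promoter for every drug from a long DE table.

    ``de`` is the concatenated output of :func:`ontarget.diffexpr.fit_de`
    (index promoter, columns contrast/lfc/p/q/sign).  ``contrast_map`` maps
    drug name to the four contrast names, e.g.::

        {"atorvastatin": {"kd1": "kd1_vs_ctrl", "kd2": "kd2_vs_ctrl",
                          "6h": "ato_6h_vs_ctrl", "48h": "ato_48h_vs_ctrl"}}

    Returns one row per promoter x drug with label, kd_consensus and
    drug_sign.  A missing contrast raises naming it.
    """
    if de.empty:
        return pd.DataFrame(
            columns=["entity_id", "drug", "cell_line", "label", "kd_consensus", "drug_sign"]
        )
    signs = de.pivot_table(index=de.index, columns="contrast", values="sign", aggfunc="first")
    rows = []
    for drug, cmap in contrast_map.items():
        for key in ("kd1", "kd2", "6h", "48h"):
            if key not in cmap or cmap[key] not in signs.columns:
                raise ValueError(f"drug {drug}: missing contrast for {key!r}")
        sub = signs[[cmap["kd1"], cmap["kd2"], cmap["6h"], cmap["48h"]]].fillna(0).astype(int)
        for pid, (a, b, c, d) in sub.iterrows():
            label, k, ds = classify(SignVector(a, b, c, d), kd_both=kd_both)
            rows.append((pid, drug, cell_line, label, k, ds))
    return pd.DataFrame(
        rows, columns=["entity_id", "drug", "cell_line", "label", "kd_consensus", "drug_sign"]
    )


def summarize_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-drug label counts (the on-/off-target summary table)."""
    if calls.empty:
        return pd.DataFrame(columns=["drug", *LABELS])
    tab = calls.pivot_table(index="drug", columns="label", values="entity_id", aggfunc="count").fillna(0).astype(int)
    for lab in LABELS:
        if lab not in tab.columns:
            tab[lab] = 0
    return tab[list(LABELS)].reset_index()


def shared_responders(calls: pd.DataFrame, min_statins: int = 2) -> dict[str, set[str]]:
    """Entities carrying the same on/off label under at least ``min_statins`` drugs.

    Returns a dict mapping label (on_up/on_down/off_up/off_down) to the set
    of entity IDs shared across >= min_statins drugs with that exact label.
    """
    out: dict[str, set[str]] = {}
    drugs = calls["drug"].unique()
    for label in ("on_up", "on_down", "off_up", "off_down"):
        per_drug = {
            drug: set(calls[(calls.drug == drug) & (calls.label == label)]["entity_id"])
            for drug in drugs
        }
        shared: set[str] = set()
        if min_statins <= len(drugs):
            counts: dict[str, int] = {}
            for members in per_drug.values():
                for e in members:
                    counts[e] = counts.get(e, 0) + 1
            shared = {e for e, c in counts.items() if c >= min_statins}
        out[label] = shared
    return out


def shared_across_cells(calls_by_cell: dict[str, pd.DataFrame], min_statins: int = 2) -> dict[str, set[str]]:
    """Entities shared (same label, >= min_statins drugs) in every cell line."""
    per_cell = [shared_responders(c, min_statins=min_statins) for c in calls_by_cell.values()]
    out: dict[str, set[str]] = {}
    for label in ("on_up", "on_down", "off_up", "off_down"):
        sets = [pc[label] for pc in per_cell]
        out[label] = set.intersection(*sets) if sets else set()
    return out
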