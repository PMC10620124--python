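"""Cancer x treatment interaction taxonomy and directional DRL set overlaps.

Each lipid of one cell line carries two significance-gated directions:

* the *cancer effect* — Up/Down/none from the contrast of the untreated
  cancer line against the healthy control, and
* the *treatment effect* — Up/Down/none from the contrast of the treated
  line against its untreated counterpart.

The pair maps onto five mutually exclusive, exhaustive categories:

=====================  ==============================================
``moderates``          both effects called, opposite directions
                       (treatment reverses the cancer effect)
``amplifies``          both effects called, same direction
``no_treatment_effect``  cancer effect only
``side_effect``        treatment effect only
``unaffected``         neither effect called
=====================  ==============================================

A lipid that was *excluded* from one contrast by the minimum-replicate
rule (rather than merely non-significant) still gets direction ``none``
there but is flagged ``not_evaluable`` so absence of evidence stays
distinguishable from evidence of no effect.

:func:`overlap_analysis` computes UpSet-style exact-combination counts
over directional DRL sets, optionally requiring concordant direction in
all member sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .errors import ValidationError

__all__ = [
    "CATEGORIES",
    "DRLSet",
    "classify_interaction",
    "interaction_counts",
    "drl_set",
    "overlap_analysis",
]

CATEGORIES = (
    "moderates",
    "amplifies",
    "no_treatment_effect",
    "side_effect",
    "unaffected",
)


def interaction_category(cancer_direction: str, treatment_direction: str) -> str:
    """Map a (cancer, treatment) direction pair to its category."""
    c, t = cancer_direction, treatment_direction
    for d in (c, t):
        if d not in ("Up", "Down", "none"):
            raise ValidationError(f"invalid direction {d!r}")
    if c != "none" and t != "none":
        return "moderates" if c != t else "amplifies"
    if c != "none":
        return "no_treatment_effect"
    if t != "none":
        return "side_effect"
    return "unaffected"


def _direction_map(contrast: pd.DataFrame) -> tuple[dict[str, str], set[str]]:
    directions = dict(zip(contrast["lipid"], contrast["direction"]))
    evaluable = set(contrast["lipid"])
    return directions, evaluable


def classify_interaction(
    cancer_contrast: pd.DataFrame,
    treatment_contrast: pd.DataFrame,
    cell_line: str | None = None,
) -> pd.DataFrame:
    """Classify every lipid of one cell line into the five-way taxonomy.

    ``cancer_contrast`` is the line's untreated-vs-healthy-control contrast
    and ``treatment_contrast`` its treated-vs-untreated contrast (both as
    produced by :func:`lipidiff.differential.compute_contrast`).  When both
    carry group attrs, their test cell lines must agree.

    Returns one row per lipid in either contrast's eligible set, sorted by
    lipid name, with columns ``lipid, lipid_class, lipid_category,
    cancer_direction, treatment_direction, category, not_evaluable_cancer,
    not_evaluable_treatment``.
    """
    lines = []
    for df, which in ((cancer_contrast, "test"), (treatment_contrast, "test")):
        group = df.attrs.get("test_group")
        if group is not None:
            lines.append(group[0])
    if cell_line is not None:
        lines.append(cell_line)
    if len(set(lines)) > 1:
        raise ValidationError(f"contrasts are from different cell lines: {set(lines)}")

    cancer_dir, cancer_eval = _direction_map(cancer_contrast)
    treat_dir, treat_eval = _direction_map(treatment_contrast)
    annot = {}
    for df in (cancer_contrast, treatment_contrast):
        for row in df.itertuples(index=False):
            annot[row.lipid] = (row.lipid_class, row.category)

    records = []
    for lipid in sorted(cancer_eval | treat_eval):
        c = cancer_dir.get(lipid, "none")
        t = treat_dir.get(lipid, "none")
        lipid_class, lipid_category = annot[lipid]
        records.append(
            {
                "lipid": lipid,
                "lipid_class": lipid_class,
                "lipid_category": lipid_category,
                "cancer_direction": c,
                "treatment_direction": t,
                "category": interaction_category(c, t),
                "not_evaluable_cancer": lipid not in cancer_eval,
                "not_evaluable_treatment": lipid not in treat_eval,
            }
        )
    calls = pd.DataFrame.from_records(
        records,
        columns=[
            "lipid",
            "lipid_class",
            "lipid_category",
            "cancer_direction",
            "treatment_direction",
            "category",
            "not_evaluable_cancer",
            "not_evaluable_treatment",
        ],
    )
    if lines:
        calls.attrs["cell_line"] = lines[0]
    return calls


def interaction_counts(calls: pd.DataFrame, strict: bool = False) -> dict[str, int]:
    """Per-category call counts.

    ``strict=True`` drops lipids that were not evaluable in one of the two
    contrasts before counting, so only fully evidenced calls are tallied.
    """
    subset = calls
    if strict:
        subset = calls[
            ~calls["not_evaluable_cancer"] & ~calls["not_evaluable_treatment"]
        ]
    counts = subset["category"].value_counts().to_dict()
    return {cat: int(counts.get(cat, 0)) for cat in CATEGORIES}


@dataclass(frozen=True)
class DRLSet:
    """A labelled set of DRLs with their Up/Down directions."""

    label: str
    members: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        bad = {d for d in self.members.values() if d not in ("Up", "Down")}
        if bad:
            raise ValidationError(f"DRLSet directions must be Up/Down, got {bad}")


def drl_set(contrast: pd.DataFrame, label: str | None = None) -> DRLSet:
    """Directional DRL set of one contrast."""
    drls = contrast[contrast["is_drl"]]
    if label is None:
        test = contrast.attrs.get("test_group")
        label = f"{test[0]}:{test[1]}" if test else "contrast"
    return DRLSet(label=label, members=dict(zip(drls["lipid"], drls["direction"])))


def overlap_analysis(sets: list[DRLSet], mode: str = "any_direction") -> pd.DataFrame:
    """UpSet-style exact-combination counts over directional DRL sets.

    Every lipid is assigned to the exact combination of sets containing it,
    and each non-empty combination is reported with its count
    (``n`` column, ``sets`` holds the member labels as a tuple).  In
    ``concordant`` mode lipids whose direction is identical across all
    member sets are split into ``n_up``/``n_down``; the rest are counted
    as ``n_discordant``.
    """
    if len(sets) < 2:
        raise ValidationError("overlap analysis needs >= 2 sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate set labels: {labels}")
    if mode not in ("any_direction", "concordant"):
        raise ValidationError(f"unknown mode {mode!r}")

    by_lipid: dict[str, dict[str, str]] = {}
    for s in sets:
        for lipid, direction in s.members.items():
            by_lipid.setdefault(lipid, {})[s.label] = direction

    combos: dict[tuple[str, ...], dict[str, int]] = {}
    for lipid, memberships in by_lipid.items():
        combo = tuple(l for l in labels if l in memberships)
        entry = combos.setdefault(combo, {"n": 0, "n_up": 0, "n_down": 0, "n_discordant": 0})
        entry["n"] += 1
        directions = set(memberships.values())
        if directions == {"Up"}:
            entry["n_up"] += 1
        elif directions == {"Down"}:
            entry["n_down"] += 1
        else:
            entry["n_discordant"] += 1

    rows = []
    for r in range(len(labels), 0, -1):
        for combo in combinations(labels, r):
            entry = combos.get(tuple(combo))
            if entry is None:
                continue
            row = {"sets": tuple(combo), "degree": r, "n": entry["n"]}
            if mode == "concordant":
                row.update(
                    n_up=entry["n_up"],
                    n_down=entry["n_down"],
                    n_discordant=entry["n_discordant"],
                )
            rows.append(row)
    columns = ["sets", "degree", "n"] + (
        ["n_up", "n_down", "n_discordant"] if mode == "concordant" else []
    )
    return pd.DataFrame(rows, columns=columns)


def membership_matrix(sets: list[DRLSet]) -> pd.DataFrame:
    """Lipid x set membership matrix (directions as strings, '' = absent).

    UpSet-plot-ready export: one row per lipid appearing in any set.
    """
    labels = [s.label for s in sets]
    lipids = sorted({l for s in sets for l in s.members})
    data = {
        s.label: [s.members.get(l, "") for l in lipids] for s in sets
    }
    return pd.DataFrame(data, index=pd.Index(lipids, name="lipid"), columns=labels)
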