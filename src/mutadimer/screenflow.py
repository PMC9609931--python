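"""Screening triage: candidate ingestion, descriptor filters, and the
wild-type-versus-mutant docking-score differential.

Descriptor values (blood-brain-barrier logBB, solubility, logP in
n-octanol and cyclohexane, ...) are ingested from upstream predictors,
never computed here; an optional surrogate estimates logBB from logP and
TPSA when SMILES are available, and says so.  Docking scores come in two
orientations: "fitness" (higher = better pose) and "affinity" (lower =
better); the mutant-specificity differential respects the declared
orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError, InputError

CORE_DESCRIPTORS = ("lgBB", "SOLY", "logP_oct", "logP_chex")
_RESERVED = {"id", "smiles", "score_wt", "score_mut"}


@dataclass
class Candidate:
    id: str
    smiles: str | None = None
    descriptors: dict = field(default_factory=dict)
    score_wt: float | None = None
    score_mut: float | None = None


@dataclass(frozen=True)
class FilterRule:
    descriptor: str
    comparator: str    # ">=" or "<="
    threshold: float

    def __post_init__(self):
        if self.comparator not in (">=", "<="):
            raise ConfigError(f"comparator must be >= or <=, "
                              f"got {self.comparator!r}")

    def passes(self, value: float) -> bool:
        return value >= self.threshold if self.comparator == ">=" \
            else value <= self.threshold


DEFAULT_BBB_RULES = [FilterRule("lgBB", ">=", -1.0)]  # placeholder convention


def load_candidates(path) -> list[Candidate]:
    """Read a candidate table CSV (id + descriptor columns, optional
    smiles/score_wt/score_mut).  Missing cells stay absent, never imputed."""
    table = pd.read_csv(path)
    if "id" not in table.columns:
        raise InputError("candidate CSV needs an 'id' column")
    desc_cols = [c for c in table.columns if c not in _RESERVED]
    if not desc_cols:
        raise InputError("candidate CSV needs at least one descriptor column")
    ids = table["id"].astype(str)
    if ids.duplicated().any():
        dup = sorted(ids[ids.duplicated()].unique())
        raise InputError(f"duplicate candidate ids: {dup}")
    out = []
    for _, row in table.iterrows():
        desc = {c: float(row[c]) for c in desc_cols if pd.notna(row[c])}
        out.append(Candidate(
            id=str(row["id"]),
            smiles=(str(row["smiles"]) if "smiles" in table.columns
                    and pd.notna(row["smiles"]) else None),
            descriptors=desc,
            score_wt=(float(row["score_wt"]) if "score_wt" in table.columns
                      and pd.notna(row["score_wt"]) else None),
            score_mut=(float(row["score_mut"]) if "score_mut" in table.columns
                       and pd.notna(row["score_mut"]) else None)))
    return out


def apply_filters(candidates: list[Candidate], rules: list[FilterRule],
                  missing_policy: str = "drop"):
    """All-rules-must-pass triage with a per-candidate audit table.

    ``missing_policy`` decides what a missing descriptor does: "drop"
    fails the rule, "keep" passes it.  Returns ``(passed, audit)``;
    the audit has one row per candidate x rule.
    """
    if missing_policy not in ("drop", "keep"):
        raise ConfigError(f"unknown missing_policy {missing_policy!r}")
    known = {d for c in candidates for d in c.descriptors}
    for rule in rules:
        if candidates and rule.descriptor not in known:
            raise ConfigError(
                f"rule references unknown descriptor {rule.descriptor!r}")
    audit_rows = []
    passed = []
    for cand in candidates:
        ok = True
        for rule in rules:
            value = cand.descriptors.get(rule.descriptor)
            if value is None:
                outcome = missing_policy == "keep"
                note = "missing"
            else:
                outcome = rule.passes(value)
                note = ""
            audit_rows.append({"id": cand.id, "descriptor": rule.descriptor,
                               "comparator": rule.comparator,
                               "threshold": rule.threshold, "value": value,
                               "passed": outcome, "note": note})
            ok = ok and outcome
        if ok:
            passed.append(cand)
    audit = pd.DataFrame(audit_rows, columns=["id", "descriptor",
                                              "comparator", "threshold",
                                              "value", "passed", "note"])
    return passed, audit


def specificity_differential(candidates: list[Candidate],
                             orientation: str, top_k: int | None = None):
    """Mutant-binding advantage Delta = score_mut - score_wt per candidate.

    "fitness" orientation: positive Delta = mutant-specific; "affinity"
    orientation: negative Delta = mutant-specific.  Returns a DataFrame
    ranked most-mutant-specific first, with a ``mutant_specific`` flag.
    """
    if orientation not in ("fitness", "affinity"):
        raise ConfigError(f"orientation must be 'fitness' or 'affinity', "
                          f"got {orientation!r}")
    rows = []
    for cand in candidates:
        if cand.score_wt is None or cand.score_mut is None:
            continue
        delta = cand.score_mut - cand.score_wt
        specific = delta > 0 if orientation == "fitness" else delta < 0
        rows.append({"id": cand.id, "score_wt": cand.score_wt,
                     "score_mut": cand.score_mut, "delta": delta,
                     "mutant_specific": specific})
    if not rows:
        raise InputError("no candidates with both scores")
    table = pd.DataFrame(rows)
    ascending = orientation == "affinity"
    table = table.sort_values("delta", ascending=ascending,
                              kind="mergesort").reset_index(drop=True)
    table["rank"] = table.index + 1
    return table.head(top_k) if top_k else table


def logbb_surrogate(logp: float, tpsa: float) -> float:
    """Literature-style logBB surrogate: 0.152*clogP - 0.0148*TPSA + 0.139
    (Clark's polar-surface-area model).  Clearly a surrogate for a
    predicted descriptor, shipped so the triage runs without proprietary
    predictors."""
    if not (math.isfinite(logp) and math.isfinite(tpsa)):
        raise ValueError("logP and TPSA must be finite")
    return 0.152 * logp - 0.0148 * tpsa + 0.139
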