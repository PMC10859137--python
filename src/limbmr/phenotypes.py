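"""Phenotype ascertainment from coded health records, and unrelated-set selection.

Case/control status is derived from (vocabulary, code) records under two
definition tiers: *broad* (hospital ICD10/OPCS4 plus GP and self-report, to
maximise sample size) and *specific* (hospital episode codes only, for case
certainty).  Relatedness is removed by greedily pruning a kinship graph,
preferentially dropping the individual with the most remaining relatives so
that as many individuals as possible are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CodeList",
    "CaseStatus",
    "RecordError",
    "ascertain_cases",
    "select_unrelated",
    "load_code_lists",
    "packaged_code_lists",
    "KINSHIP_THIRD_DEGREE",
]

KNOWN_VOCABULARIES = ("ICD10", "OPCS4", "GP", "SELF")

#: KING kinship coefficient above which a pair is third-degree or closer.
KINSHIP_THIRD_DEGREE = 0.0442

DEFAULT_TIER_RULE = {
    "specific": frozenset({"ICD10", "OPCS4"}),
    "broad": frozenset({"ICD10", "OPCS4", "GP", "SELF"}),
}


class RecordError(ValueError):
    """Malformed health-record or code-list input."""


def _normalize(code: str) -> str:
    """Case- and dot-insensitive code form (ICD-10 dialects differ)."""
    return str(code).upper().replace(".", "").strip()


@dataclass
class CodeList:
    """Clinical code list defining one condition.

    ``entries`` are (vocabulary, code, match_mode) with match_mode ``exact``
    or ``prefix``; prefix matching honours the ICD-10 hierarchy, so a
    4-character record matches its 3-character prefix entry.  Self-report
    codes always match exactly.
    """

    condition_name: str
    entries: list[tuple[str, str, str]]
    tier_rule: dict[str, frozenset] = field(
        default_factory=lambda: dict(DEFAULT_TIER_RULE)
    )

    def __post_init__(self) -> None:
        for vocab, code, mode in self.entries:
            if vocab not in KNOWN_VOCABULARIES:
                raise RecordError(
                    f"{self.condition_name}: unknown vocabulary {vocab!r} in code list"
                )
            if mode not in ("exact", "prefix"):
                raise RecordError(
                    f"{self.condition_name}: unknown match mode {mode!r} for {code!r}"
                )
            if vocab == "SELF" and mode != "exact":
                raise RecordError(
                    f"{self.condition_name}: self-report code {code!r} must use "
                    "exact matching"
                )
        if not self.tier_rule["specific"] <= self.tier_rule["broad"]:
            raise RecordError("broad tier must allow a superset of specific's vocabularies")


@dataclass
class CaseStatus:
    condition_name: str
    tier: str
    status: np.ndarray  # binary over individuals

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())


def ascertain_cases(
    records: pd.DataFrame,
    code_list: CodeList,
    tier: str,
    n_individuals: int,
) -> CaseStatus:
    """Flag each of ``n_individuals`` as case iff >=1 record matches the list.

    Only entries whose vocabulary is allowed by the tier are consulted.
    Records in vocabularies outside the known set raise, naming the rows.
    """
    if tier not in code_list.tier_rule:
        raise RecordError(f"unknown tier {tier!r}; expected one of {sorted(code_list.tier_rule)}")
    allowed = code_list.tier_rule[tier]
    status = np.zeros(n_individuals, dtype=int)
    if len(records) == 0:
        return CaseStatus(code_list.condition_name, tier, status)

    unknown = ~records["vocabulary"].isin(KNOWN_VOCABULARIES)
    if unknown.any():
        rows = records.index[unknown].tolist()[:20]
        raise RecordError(
            f"unknown vocabulary tag(s) {sorted(records.loc[unknown, 'vocabulary'].unique())} "
            f"in record rows {rows}"
        )

    codes = records["code"].map(_normalize)
    matched = np.zeros(len(records), dtype=bool)
    for vocab, code, mode in code_list.entries:
        if vocab not in allowed:
            continue
        in_vocab = (records["vocabulary"] == vocab).to_numpy()
        target = _normalize(code)
        if mode == "exact":
            hit = (codes == target).to_numpy()
        else:
            hit = codes.str.startswith(target).to_numpy()
        matched |= in_vocab & hit
    ids = records.loc[matched, "id"].unique()
    status[np.asarray(ids, dtype=int)] = 1
    return CaseStatus(code_list.condition_name, tier, status)


def select_unrelated(
    kinship_pairs: list[tuple[int, int, float]],
    threshold: float = KINSHIP_THIRD_DEGREE,
) -> set[int]:
    """Maximal unrelated id set by greedy max-degree removal.

    While any pair at or above the threshold remains, the individual with
    the largest number of remaining above-threshold relatives is removed;
    ties are broken by removing the largest id (deterministic).  The
    returned set (over ids appearing in the pairs) is an independent set of
    the kinship graph.
    """
    adj: dict[int, set[int]] = {}
    for a, b, coef in kinship_pairs:
        if a == b:
            raise RecordError(f"self-pair ({a},{a}) in kinship list")
        if coef >= threshold:
            adj.setdefault(int(a), set()).add(int(b))
            adj.setdefault(int(b), set()).add(int(a))
    retained = set(adj)
    # isolated ids (all edges below threshold) are retained
    for a, b, _ in kinship_pairs:
        retained.add(int(a))
        retained.add(int(b))
    while True:
        deg = {i: len(nbrs) for i, nbrs in adj.items() if nbrs}
        if not deg:
            break
        worst = max(deg)  # tie-break: largest id
        worst_deg = 0
        for i, d in deg.items():
            if d > worst_deg or (d == worst_deg and i > worst):
                worst, worst_deg = i, d
        retained.discard(worst)
        for nbr in adj.pop(worst, set()):
            adj[nbr].discard(worst)
    return retained


def load_code_lists(path) -> dict[str, CodeList]:
    """Read condition code lists from TSV (condition, vocabulary, code, match_mode)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"condition", "vocabulary", "code", "match_mode"}
    missing = required - set(df.columns)
    if missing:
        raise RecordError(f"code-list file missing column(s) {sorted(missing)}")
    out: dict[str, CodeList] = {}
    for name, grp in df.groupby("condition", sort=False):
        out[name] = CodeList(
            condition_name=name,
            entries=list(grp[["vocabulary", "code", "match_mode"]].itertuples(index=False, name=None)),
        )
    return out


def packaged_code_lists() -> dict[str, CodeList]:
    """Illustrative code lists for the four upper-limb conditions.

    The ICD-10 anchors (M75.0 adhesive capsulitis, M72.0 Dupuytren, M65.3
    trigger finger, G56.0 carpal tunnel) are representative, not an
    authoritative clinical code set.
    """
    with resources.as_file(
        resources.files("limbmr.data").joinpath("code_lists.tsv")
    ) as p:
        return load_code_lists(p)
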