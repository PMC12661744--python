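"""Arm-level data model, long-format I/O, study filters and network eligibility.

The universal input is arm-level binary outcome data in long format: one row
per study arm carrying a study label, a treatment label, an event count and
a sample size.  Everything downstream (graph construction, node-splitting,
classification) consumes the validated :class:`NMADataset` built here.

Two screening steps mirror how an analysable network is selected:

* :func:`filter_event_risk` removes every study with an observed event risk
  below ``lo`` or above ``hi`` (defaults 15% / 85%) in at least one arm —
  the separation guard for logistic models — and reports whether the
  remaining network is still connected;
* :func:`check_eligibility` checks treatment count, studies-vs-treatments,
  connectivity and the existence of a closed loop not informed exclusively
  by multi-arm studies.  Each criterion is configurable because published
  selection rules differ in wording.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("nmasplit")

__all__ = [
    "ArmRecord",
    "NMADataset",
    "FilterReport",
    "EligibilityRules",
    "EligibilityReport",
    "ValidationError",
    "read_long_format",
    "read_wide_format",
    "filter_event_risk",
    "check_eligibility",
    "write_results_table",
    "read_results_table",
    "load_column_mapping",
]

#: canonical long-format column names
COLUMNS = ("study", "treatment", "events", "sample_size")


class ValidationError(ValueError):
    """Raised when input data violate the arm-level data model."""


@dataclass(frozen=True)
class ArmRecord:
    """One study arm: events out of sample_size under a treatment."""

    study: str
    treatment: str
    events: int
    sample_size: int

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValidationError(
                f"study {self.study!r}: sample_size must be >= 1"
            )
        if not 0 <= self.events <= self.sample_size:
            raise ValidationError(
                f"study {self.study!r}: events must satisfy "
                f"0 <= events <= sample_size"
            )

    @property
    def risk(self) -> float:
        return self.events / self.sample_size


class NMADataset:
    """Validated arm-level dataset for one treatment network.

    Parameters
    ----------
    arms:
        Arm records, or a DataFrame with the canonical columns
        ``study, treatment, events, sample_size``.
    outcome_direction:
        ``"beneficial"`` or ``"harmful"``; metadata only, never used in
        estimation.
    name:
        Optional network identifier used in logs and batch runs.
    """

    def __init__(
        self,
        arms: Iterable[ArmRecord] | pd.DataFrame,
        outcome_direction: str = "beneficial",
        name: str | None = None,
        _validate: bool = True,
    ) -> None:
        if isinstance(arms, pd.DataFrame):
            df = arms.loc[:, list(COLUMNS)].copy()
        else:
            df = pd.DataFrame(
                [(a.study, a.treatment, a.events, a.sample_size) for a in arms],
                columns=list(COLUMNS),
            )
        df["study"] = df["study"].astype(str)
        df["treatment"] = df["treatment"].astype(str)
        if len(df):
            df["events"] = df["events"].astype(int)
            df["sample_size"] = df["sample_size"].astype(int)
        # canonical row order: rows never influence results
        df = df.sort_values(["study", "treatment"], kind="mergesort").reset_index(
            drop=True
        )
        if outcome_direction not in ("beneficial", "harmful"):
            raise ValidationError(
                "outcome_direction must be 'beneficial' or 'harmful'"
            )
        self._df = df
        self.outcome_direction = outcome_direction
        self.name = name
        if _validate:
            self.validate()

    # -- views -------------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """Canonical long-format view (copy)."""
        return self._df.copy()

    @property
    def arms(self) -> list[ArmRecord]:
        return [
            ArmRecord(r.study, r.treatment, int(r.events), int(r.sample_size))
            for r in self._df.itertuples(index=False)
        ]

    @property
    def studies(self) -> list[str]:
        return sorted(self._df["study"].unique())

    @property
    def treatments(self) -> list[str]:
        """Treatment labels in the global (lexicographic) coding order."""
        return sorted(self._df["treatment"].unique())

    @property
    def is_empty(self) -> bool:
        return len(self._df) == 0

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NMADataset):
            return NotImplemented
        return (
            self._df.equals(other._df)
            and self.outcome_direction == other.outcome_direction
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"NMADataset(studies={len(self.studies)}, "
            f"treatments={len(self.treatments)}, arms={len(self)})"
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Enforce the data-model invariants; raises :class:`ValidationError`."""
        df = self._df
        if len(df) == 0:
            raise ValidationError("dataset is empty")
        bad = df[(df["sample_size"] < 1)]
        if len(bad):
            raise ValidationError(
                f"study {bad.iloc[0]['study']!r}: sample_size must be >= 1"
            )
        bad = df[(df["events"] < 0) | (df["events"] > df["sample_size"])]
        if len(bad):
            raise ValidationError(
                f"study {bad.iloc[0]['study']!r}: events must satisfy "
                f"0 <= events <= sample_size"
            )
        dup = df.duplicated(subset=["study", "treatment"])
        if dup.any():
            s = df.loc[dup, "study"].iloc[0]
            raise ValidationError(f"study {s!r}: duplicate (study, treatment) pair")
        n_arms = df.groupby("study")["treatment"].nunique()
        single = n_arms[n_arms < 2]
        if len(single):
            raise ValidationError(
                f"study {single.index[0]!r}: every study must have >= 2 arms"
            )
        if df["treatment"].nunique() < 2:
            raise ValidationError("dataset must contain >= 2 distinct treatments")

    # -- helpers -----------------------------------------------------------

    def study_treatments(self) -> dict[str, tuple[str, ...]]:
        """Design (sorted treatment tuple) of every study."""
        return {
            s: tuple(sorted(g["treatment"]))
            for s, g in self._df.groupby("study")
        }

    def subset(self, studies: Iterable[str], _validate: bool = True) -> "NMADataset":
        keep = set(studies)
        df = self._df[self._df["study"].isin(keep)].reset_index(drop=True)
        return NMADataset(
            df, self.outcome_direction, name=self.name, _validate=_validate
        )

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self._df.to_csv(path, sep=sep, index=False)


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------

#: accepted header synonyms for the canonical columns
_SYNONYMS: dict[str, tuple[str, ...]] = {
    "study": ("study", "study_id", "studyid", "id", "trial"),
    "treatment": ("treatment", "t", "arm", "intervention"),
    "events": ("events", "r", "event", "responders"),
    "sample_size": ("sample_size", "n", "total", "sampleSize", "samplesize"),
}


def load_column_mapping(path: str | Path) -> dict[str, str]:
    """Load a canonical-column -> file-column mapping from YAML or JSON."""
    text = Path(path).read_text()
    mapping = yaml.safe_load(text)
    if not isinstance(mapping, Mapping):
        raise ValidationError(f"column mapping in {path} must be a mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def _resolve_columns(
    df: pd.DataFrame, mapping: Mapping[str, str] | None
) -> pd.DataFrame:
    mapping = dict(mapping or {})
    resolved: dict[str, str] = {}
    lower = {c.lower(): c for c in df.columns}
    for canon in COLUMNS:
        if canon in mapping:
            src = mapping[canon]
            if src not in df.columns:
                raise ValidationError(
                    f"mapped column {src!r} for {canon!r} not found in file"
                )
            resolved[canon] = src
            continue
        for syn in _SYNONYMS[canon]:
            if syn.lower() in lower:
                resolved[canon] = lower[syn.lower()]
                break
        else:
            raise ValidationError(
                f"no column found for {canon!r}; provide a column mapping"
            )
    out = df[[resolved[c] for c in COLUMNS]].copy()
    out.columns = list(COLUMNS)
    return out


def read_long_format(
    path: str | Path,
    column_mapping: Mapping[str, str] | str | Path | None = None,
    sep: str | None = None,
    outcome_direction: str = "beneficial",
    name: str | None = None,
) -> NMADataset:
    """Read a long-format delimited file into a validated :class:`NMADataset`.

    ``sep=None`` sniffs comma/tab.  ``column_mapping`` maps canonical names
    (study, treatment, events, sample_size) to the file's headers, given
    inline or as a YAML/JSON file path; common synonyms are recognised
    automatically.
    """
    path = Path(path)
    if isinstance(column_mapping, (str, Path)):
        column_mapping = load_column_mapping(column_mapping)
    try:
        df = pd.read_csv(path, sep=sep, engine="python")
    except Exception as exc:  # noqa: BLE001 - surface the parse location
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    df = _resolve_columns(df, column_mapping)
    for col in ("events", "sample_size"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            line = int(coerced.index[coerced.isna()][0]) + 2  # header + 1-based
            raise ValidationError(
                f"{path}: malformed {col!r} value on line {line}"
            )
        df[col] = coerced.astype(int)
    return NMADataset(
        df, outcome_direction=outcome_direction, name=name or path.stem
    )


def read_wide_format(
    path: str | Path,
    sep: str | None = None,
    outcome_direction: str = "beneficial",
    name: str | None = None,
) -> NMADataset:
    """Read a one-row-per-study file and normalise it to long format.

    Expected headers: ``study`` plus repeated ``t1,e1,n1,t2,e2,n2,...``
    (treatment label, events, sample size per arm); empty cells mark absent
    arms of shorter studies.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "study" not in cols:
        raise ValidationError(f"{path}: wide format requires a 'study' column")
    k = 1
    rows = []
    while f"t{k}" in cols and f"e{k}" in cols and f"n{k}" in cols:
        sub = df[[cols["study"], cols[f"t{k}"], cols[f"e{k}"], cols[f"n{k}"]]]
        sub.columns = list(COLUMNS)
        rows.append(sub.dropna(subset=["treatment"]))
        k += 1
    if not rows:
        raise ValidationError(f"{path}: no arm columns t1/e1/n1 found")
    long = pd.concat(rows, ignore_index=True)
    long["events"] = long["events"].astype(float).astype(int)
    long["sample_size"] = long["sample_size"].astype(float).astype(int)
    return NMADataset(
        long, outcome_direction=outcome_direction, name=name or path.stem
    )


# --------------------------------------------------------------------------
# Filters & eligibility
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterReport:
    """Outcome of the event-risk screen."""

    removed_studies: tuple[tuple[str, str], ...]  # (study, reason)
    retained: NMADataset
    connectivity_intact: bool
    all_removed: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "removed_studies": [
                    {"study": s, "reason": r} for s, r in self.removed_studies
                ],
                "n_retained_studies": 0
                if self.retained.is_empty
                else len(self.retained.studies),
                "connectivity_intact": self.connectivity_intact,
                "all_removed": self.all_removed,
            },
            indent=2,
        )


def filter_event_risk(
    ds: NMADataset, lo: float = 0.15, hi: float = 0.85
) -> FilterReport:
    """Remove studies with an arm event risk strictly below lo or above hi.

    A study is dropped as soon as *any* of its arms is outside [lo, hi];
    arms exactly at the bounds are retained (the rule is "below"/"above").
    Connectivity of the retained network is reported; when every study is
    removed the report carries ``all_removed=True`` and an empty retained
    dataset (the network is then excluded outright).
    """
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("require 0 <= lo < hi <= 1")
    df = ds.frame
    risk = df["events"] / df["sample_size"]
    flagged = df.loc[(risk < lo) | (risk > hi), "study"]
    removed = []
    for s in sorted(set(flagged)):
        removed.append(
            (s, f"event risk below {lo:g} or above {hi:g} in at least one arm")
        )
        logger.info("filter_event_risk: removing study %r", s)
    keep = [s for s in ds.studies if s not in {r[0] for r in removed}]
    retained = ds.subset(keep, _validate=False)
    all_removed = retained.is_empty
    if all_removed:
        logger.warning(
            "filter_event_risk: all studies removed; network excluded"
        )
        connectivity = False
    else:
        retained.validate()
        import networkx as nx

        from .geometry import build_network

        # judged against the *original* treatment set: a treatment left
        # without studies disconnects the network
        g = build_network(retained).graph()
        g.add_nodes_from(ds.treatments)
        connectivity = nx.is_connected(g)
        if not connectivity:
            logger.warning(
                "filter_event_risk: network connectivity compromised after "
                "excluding studies"
            )
    return FilterReport(
        removed_studies=tuple(removed),
        retained=retained,
        connectivity_intact=connectivity,
        all_removed=all_removed,
    )


@dataclass(frozen=True)
class EligibilityRules:
    """Configurable eligibility thresholds.

    ``min_treatments`` and the studies-vs-treatments comparison are
    deliberately configuration: published selection wordings disagree
    (one phrasing implies ">= 3 treatments and #studies >= #treatments",
    another ">= 4 treatments and more studies than treatments").  Defaults
    use the permissive reading.
    """

    min_treatments: int = 3
    studies_vs_treatments: str = "ge"  # "ge": studies >= treatments; "gt": >
    require_connected: bool = True
    require_valid_loop: bool = True


@dataclass(frozen=True)
class EligibilityReport:
    """Per-criterion pass/fail flags; overall is their conjunction."""

    enough_treatments: bool
    enough_studies: bool
    connected: bool
    has_valid_loop: bool
    overall_eligible: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "overall_eligible",
            self.enough_treatments
            and self.enough_studies
            and self.connected
            and self.has_valid_loop,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "enough_treatments": self.enough_treatments,
                "enough_studies": self.enough_studies,
                "connected": self.connected,
                "has_valid_loop": self.has_valid_loop,
                "overall_eligible": self.overall_eligible,
            },
            indent=2,
        )


def check_eligibility(
    ds: NMADataset, rules: EligibilityRules | None = None
) -> EligibilityReport:
    """Evaluate the network eligibility criteria; always returns a report."""
    from .geometry import build_network, has_valid_loop, is_connected

    rules = rules or EligibilityRules()
    net = build_network(ds)
    n_t = len(ds.treatments)
    n_s = len(ds.studies)
    enough_treatments = n_t >= rules.min_treatments
    enough_studies = n_s > n_t if rules.studies_vs_treatments == "gt" else n_s >= n_t
    connected = is_connected(net) if rules.require_connected else True
    loop_ok = has_valid_loop(net) if rules.require_valid_loop else True
    report = EligibilityReport(
        enough_treatments=enough_treatments,
        enough_studies=enough_studies,
        connected=connected,
        has_valid_loop=loop_ok,
    )
    logger.info("check_eligibility: %s", report.to_json().replace("\n", " "))
    return report


# --------------------------------------------------------------------------
# Results table I/O
# --------------------------------------------------------------------------

#: stable column order of the per-split-node results table
RESULT_COLUMNS = [
    "comparison",
    "n_direct_studies",
    "single_study",
    "direct_mean", "direct_sd", "direct_median", "direct_q025", "direct_q975",
    "direct_rhat",
    "indirect_mean", "indirect_sd", "indirect_median", "indirect_q025",
    "indirect_q975", "indirect_rhat",
    "if_mean", "if_sd", "if_median", "if_q025", "if_q975", "if_rhat",
    "tau_mean", "tau_sd", "tau_median", "tau_q025", "tau_q975", "tau_rhat",
    "d_di", "d_id", "index",
    "threshold", "extent", "conclusiveness", "tau_band",
]


def write_results_table(
    results: Sequence["NodeSplitResult"],  # noqa: F821
    path: str | Path,
    threshold: float | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Write one row per split node with posteriors, KLD triple and verdicts.

    Returns the DataFrame that was written.  Raises on an empty collection.
    """
    from .kld import classify_node, heterogeneity_band, low_inconsistency_threshold

    if len(results) == 0:
        raise ValueError("no results to write")
    if threshold is None:
        threshold = low_inconsistency_threshold()
    rows = []
    for res in results:
        verdict = classify_node(res, threshold)
        row: dict[str, object] = {
            "comparison": f"{res.node.comparison[0]} vs {res.node.comparison[1]}",
            "n_direct_studies": res.node.n_direct_studies,
            "single_study": res.node.single_study,
        }
        for label, summ in (
            ("direct", res.direct),
            ("indirect", res.indirect),
            ("if", res.inconsistency_factor),
            ("tau", res.tau),
        ):
            row[f"{label}_mean"] = summ.mean
            row[f"{label}_sd"] = summ.sd
            row[f"{label}_median"] = summ.median
            row[f"{label}_q025"] = summ.q025
            row[f"{label}_q975"] = summ.q975
            row[f"{label}_rhat"] = summ.rhat
        row["d_di"] = res.kld.d_di
        row["d_id"] = res.kld.d_id
        row["index"] = res.kld.index
        row["threshold"] = verdict.threshold_used
        row["extent"] = verdict.extent.value
        row["conclusiveness"] = verdict.conclusiveness.value
        row["tau_band"] = heterogeneity_band(res.tau.median)
        rows.append(row)
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    table.to_csv(path, sep=sep, index=False, float_format="%.6g")
    return table


def read_results_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read back a results table written by :func:`write_results_table`."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"results table missing columns: {missing}")
    return df[RESULT_COLUMNS]
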