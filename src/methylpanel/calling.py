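"""Sample-level result calling over duplicate qPCR wells.

A multiplex methylation-specific qPCR assay reports one CT (cycle
threshold) per channel per well: three methylation markers (mSEPT9,
mALX4, mSDC2) and the ACTB internal control.  Each subject is run in
two parallel wells.  A channel that never crosses the fluorescence
threshold is "Undetermined" and is represented in memory by ``NaN``
(the :data:`UNDETERMINED` sentinel), which never compares below any
finite cutoff.

Three call algorithms convert the two wells of a sample into a single
POSITIVE / NEGATIVE / INVALID status:

``balancing``
    positive if (ii) every well has at least one marker below its
    cutoff (45 / 38 / 40 for mSEPT9 / mALX4 / mSDC2), or (iii) mALX4
    is below 38 in at least one well, or (iv) within a single well at
    least two markers have CT < 40 with each marker's ΔCT
    (marker CT − same-well ACTB CT) below 10.
``one_half``
    positive if any single valid well has a marker below its cutoff
    (45 / 38 / 43) whose ΔCT is below 15.
``two_thirds``
    positive if both wells each have a marker below 40.67 / 36.8 /
    36.23.

All algorithms first require the ACTB internal control to be valid
(CT ≤ 40, non-strict) in both wells; otherwise the sample is INVALID
and flagged for retest.  Marker positivity itself is strict
("smaller than" the cutoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "UNDETERMINED",
    "GENES",
    "ACTB",
    "WellRecord",
    "CutoffSet",
    "SampleCall",
    "BALANCING",
    "ONE_HALF",
    "TWO_THIRDS",
    "CUTOFF_PRESETS",
    "POSITIVE",
    "NEGATIVE",
    "INVALID",
    "is_undetermined",
    "gene_positive",
    "well_valid",
    "call_balancing",
    "call_one_half",
    "call_two_thirds",
    "call_cohort",
    "single_well_positive",
    "single_well_calls",
    "DuplicateWellCaller",
]

#: In-memory sentinel for a channel that never crossed threshold.
#: NaN is used deliberately: every comparison with a finite cutoff is
#: False, so an undetermined channel can never satisfy a positivity rule.
UNDETERMINED = float("nan")

GENES = ("mSEPT9", "mALX4", "mSDC2")
ACTB = "ACTB"

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"
INVALID = "INVALID"


def is_undetermined(ct: float) -> bool:
    """True if a CT value is the undetermined sentinel."""
    return ct is None or (isinstance(ct, float) and math.isnan(ct))


@dataclass(frozen=True)
class WellRecord:
    """One qPCR reaction: CT per channel, possibly undetermined.

    Parameters
    ----------
    sample_id : str
        Subject identifier; both wells of a subject share it.
    well_index : int
        1 or 2.
    ct : mapping
        Channel name (mSEPT9, mALX4, mSDC2, ACTB) to CT value.
        Undetermined channels hold :data:`UNDETERMINED`.
    """

    sample_id: str
    well_index: int
    ct: Mapping[str, float]

    def __post_init__(self) -> None:
        for gene, value in self.ct.items():
            if not is_undetermined(value) and not value > 0:
                raise ValueError(
                    f"CT for {gene} in sample {self.sample_id} well "
                    f"{self.well_index} must be positive or undetermined, "
                    f"got {value!r}"
                )

    def get(self, gene: str) -> float:
        if gene not in self.ct:
            raise KeyError(f"unknown gene {gene!r} in well record")
        return self.ct[gene]

    def without_gene(self, gene: str) -> "WellRecord":
        """Copy of the well with one channel forced to undetermined."""
        ct = dict(self.ct)
        if gene in ct:
            ct[gene] = UNDETERMINED
        return WellRecord(self.sample_id, self.well_index, ct)


@dataclass(frozen=True)
class CutoffSet:
    """Per-gene CT cutoffs and ΔCT limit defining one call algorithm."""

    name: str
    ct_cutoff: Mapping[str, float]
    delta_ct_limit: float | None = None
    actb_validity_cutoff: float = 40.0
    # balancing rule (iv) parameters; unused by the other algorithms
    pair_ct_limit: float | None = None
    pair_delta_ct_limit: float | None = None

    def __post_init__(self) -> None:
        for gene in GENES:
            if gene not in self.ct_cutoff:
                raise ValueError(f"cutoff set {self.name!r} misses {gene}")
            c = self.ct_cutoff[gene]
            if not (math.isfinite(c) and c > 0):
                raise ValueError(f"cutoff for {gene} must be finite positive")
        if not (math.isfinite(self.actb_validity_cutoff) and self.actb_validity_cutoff > 0):
            raise ValueError("ACTB validity cutoff must be finite positive")


BALANCING = CutoffSet(
    name="balancing",
    ct_cutoff={"mSEPT9": 45.0, "mALX4": 38.0, "mSDC2": 40.0},
    pair_ct_limit=40.0,
    pair_delta_ct_limit=10.0,
)

ONE_HALF = CutoffSet(
    name="one_half",
    ct_cutoff={"mSEPT9": 45.0, "mALX4": 38.0, "mSDC2": 43.0},
    delta_ct_limit=15.0,
)

TWO_THIRDS = CutoffSet(
    name="two_thirds",
    ct_cutoff={"mSEPT9": 40.67, "mALX4": 36.8, "mSDC2": 36.23},
)

CUTOFF_PRESETS: Mapping[str, CutoffSet] = {
    "balancing": BALANCING,
    "one_half": ONE_HALF,
    "two_thirds": TWO_THIRDS,
}


@dataclass
class SampleCall:
    """Per-sample call with the rules that fired and per-well detail."""

    sample_id: str
    status: str
    fired_rules: list[str] = field(default_factory=list)
    well_positivity: dict[int, dict[str, bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status == INVALID and self.fired_rules:
            raise ValueError("INVALID call cannot carry fired rules")
        if self.status == POSITIVE and not self.fired_rules:
            raise ValueError("POSITIVE call must carry at least one fired rule")


def gene_positive(well: WellRecord, gene: str, cutoff: float) -> bool:
    """Strict positivity: CT finite and smaller than the cutoff."""
    ct = well.get(gene)
    return (not is_undetermined(ct)) and ct < cutoff


def well_valid(well: WellRecord, actb_cutoff: float = 40.0) -> bool:
    """Internal-control validity: ACTB CT finite and ≤ cutoff (non-strict)."""
    ct = well.get(ACTB)
    return (not is_undetermined(ct)) and ct <= actb_cutoff


def delta_ct(well: WellRecord, gene: str) -> float:
    """Marker CT minus the same well's ACTB CT (NaN if either undetermined)."""
    return well.get(gene) - well.get(ACTB)


def _gene_positivity(well: WellRecord, cutoffs: CutoffSet) -> dict[str, bool]:
    return {g: gene_positive(well, g, cutoffs.ct_cutoff[g]) for g in GENES}


def _require_two_wells(wells: Sequence[WellRecord]) -> None:
    if len(wells) != 2:
        raise ValueError(f"expected exactly 2 wells per sample, got {len(wells)}")


def _invalid(wells: Sequence[WellRecord], cutoffs: CutoffSet) -> SampleCall | None:
    if not all(well_valid(w, cutoffs.actb_validity_cutoff) for w in wells):
        return SampleCall(wells[0].sample_id, INVALID)
    return None


def call_balancing(wells: Sequence[WellRecord], cutoffs: CutoffSet = BALANCING) -> SampleCall:
    """Balancing algorithm over one sample's two wells.

    INVALID if either well fails the ACTB rule; otherwise POSITIVE when
    any of rules (ii)–(iv) documented in the module docstring fires.
    """
    _require_two_wells(wells)
    if (bad := _invalid(wells, cutoffs)) is not None:
        return bad
    positivity = {w.well_index: _gene_positivity(w, cutoffs) for w in wells}
    fired: list[str] = []
    if all(any(positivity[w.well_index].values()) for w in wells):
        fired.append("both_wells_positive")
    if any(gene_positive(w, "mALX4", cutoffs.ct_cutoff["mALX4"]) for w in wells):
        fired.append("alx4_single_well")
    for w in wells:
        hits = [
            g
            for g in GENES
            if (not is_undetermined(w.get(g)))
            and w.get(g) < cutoffs.pair_ct_limit
            and delta_ct(w, g) < cutoffs.pair_delta_ct_limit
        ]
        if len(hits) >= 2:
            fired.append(f"two_gene_delta_ct_well{w.well_index}")
    status = POSITIVE if fired else NEGATIVE
    return SampleCall(wells[0].sample_id, status, fired, positivity)


def call_one_half(wells: Sequence[WellRecord], cutoffs: CutoffSet = ONE_HALF) -> SampleCall:
    """One-half algorithm: any single well with a marker below its cutoff
    and ΔCT below 15 makes the sample positive."""
    _require_two_wells(wells)
    if (bad := _invalid(wells, cutoffs)) is not None:
        return bad
    fired: list[str] = []
    positivity: dict[int, dict[str, bool]] = {}
    for w in wells:
        flags = {}
        for g in GENES:
            flags[g] = (
                gene_positive(w, g, cutoffs.ct_cutoff[g])
                and delta_ct(w, g) < cutoffs.delta_ct_limit
            )
        positivity[w.well_index] = flags
        if any(flags.values()):
            fired.append(f"single_well_positive_well{w.well_index}")
    status = POSITIVE if fired else NEGATIVE
    return SampleCall(wells[0].sample_id, status, fired, positivity)


def call_two_thirds(wells: Sequence[WellRecord], cutoffs: CutoffSet = TWO_THIRDS) -> SampleCall:
    """Two-thirds algorithm: both wells must each have a positive marker."""
    _require_two_wells(wells)
    if (bad := _invalid(wells, cutoffs)) is not None:
        return bad
    positivity = {w.well_index: _gene_positivity(w, cutoffs) for w in wells}
    fired = (
        ["both_wells_positive"]
        if all(any(positivity[w.well_index].values()) for w in wells)
        else []
    )
    status = POSITIVE if fired else NEGATIVE
    return SampleCall(wells[0].sample_id, status, fired, positivity)


_ALGORITHMS = {
    "balancing": (call_balancing, BALANCING),
    "one_half": (call_one_half, ONE_HALF),
    "two_thirds": (call_two_thirds, TWO_THIRDS),
}


def single_well_positive(
    well: WellRecord, algorithm: str = "balancing", cutoffs: CutoffSet | None = None
) -> bool:
    """Single-well positivity used for duplicate-concordance analyses.

    Applies the per-well part of an algorithm's rule to one well in
    isolation: at least one marker below its cutoff (plus, for
    ``one_half``, the ΔCT condition; for ``balancing``, also the mALX4
    and two-gene ΔCT single-well rules).
    """
    if cutoffs is None:
        cutoffs = CUTOFF_PRESETS[algorithm]
    if not well_valid(well, cutoffs.actb_validity_cutoff):
        return False
    if algorithm == "one_half":
        return any(
            gene_positive(well, g, cutoffs.ct_cutoff[g])
            and delta_ct(well, g) < cutoffs.delta_ct_limit
            for g in GENES
        )
    if algorithm == "balancing":
        if any(_gene_positivity(well, cutoffs).values()):
            return True
        hits = [
            g
            for g in GENES
            if (not is_undetermined(well.get(g)))
            and well.get(g) < cutoffs.pair_ct_limit
            and delta_ct(well, g) < cutoffs.pair_delta_ct_limit
        ]
        return len(hits) >= 2
    return any(_gene_positivity(well, cutoffs).values())


def single_well_calls(
    well_table: pd.DataFrame, algorithm: str = "balancing"
) -> dict[int, list[bool]]:
    """Per-well positivity vectors for duplicate-concordance analyses.

    Returns ``{well_index: [flag per sample]}`` with samples in sorted
    order, applying :func:`single_well_positive` to each well in
    isolation.
    """
    per_sample = _records_from_table(well_table)
    out: dict[int, list[bool]] = {}
    for sample_id in sorted(per_sample):
        for rec in per_sample[sample_id]:
            out.setdefault(rec.well_index, []).append(
                single_well_positive(rec, algorithm)
            )
    return out


def _records_from_table(table: pd.DataFrame) -> dict[str, list[WellRecord]]:
    column_map = {
        "ct_msept9": "mSEPT9",
        "ct_malx4": "mALX4",
        "ct_msdc2": "mSDC2",
        "ct_actb": ACTB,
    }
    missing = [c for c in ("sample_id", "well", *column_map) if c not in table.columns]
    if missing:
        raise ValueError(f"well table misses columns: {missing}")
    per_sample: dict[str, list[WellRecord]] = {}
    for row in table.itertuples(index=False):
        ct = {gene: float(getattr(row, col)) for col, gene in column_map.items()}
        rec = WellRecord(str(row.sample_id), int(row.well), ct)
        per_sample.setdefault(rec.sample_id, []).append(rec)
    return per_sample


def call_cohort(
    well_table: pd.DataFrame,
    algorithm: str = "balancing",
    include_alx4: bool = True,
    cutoffs: CutoffSet | None = None,
) -> pd.DataFrame:
    """Call every sample of a well table with one algorithm.

    Parameters
    ----------
    well_table : DataFrame
        Long format, one row per well: ``sample_id, [group,] well,
        ct_msept9, ct_malx4, ct_msdc2, ct_actb``.  Undetermined CTs are
        NaN.
    algorithm : {"balancing", "one_half", "two_thirds"}
    include_alx4 : bool
        When False the mALX4 channel is blanked to undetermined before
        calling (marker-removal reanalysis).
    cutoffs : CutoffSet, optional
        Override the algorithm's preset cutoffs.

    Returns
    -------
    DataFrame with one row per sample: ``sample_id, [group,] status,
    fired_rules`` (semicolon-joined).  Samples without exactly two wells
    get status ``ERROR`` and are meant to be excluded (with a logged
    count) from downstream metrics.
    """
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    caller, preset = _ALGORITHMS[algorithm]
    cutoffs = cutoffs or preset
    if well_table.empty:
        cols = ["sample_id", "status", "fired_rules"]
        if "group" in well_table.columns:
            cols.insert(1, "group")
        return pd.DataFrame(columns=cols)

    groups = (
        well_table.drop_duplicates("sample_id").set_index("sample_id")["group"]
        if "group" in well_table.columns
        else None
    )
    rows = []
    for sample_id, wells in _records_from_table(well_table).items():
        if not include_alx4:
            wells = [w.without_gene("mALX4") for w in wells]
        wells = sorted(wells, key=lambda w: w.well_index)
        try:
            call = caller(wells, cutoffs)
            status, rules = call.status, ";".join(call.fired_rules)
        except ValueError:
            status, rules = "ERROR", ""
        row = {"sample_id": sample_id, "status": status, "fired_rules": rules}
        if groups is not None:
            row["group"] = groups.loc[sample_id]
        rows.append(row)
    out = pd.DataFrame(rows)
    order = ["sample_id"] + (["group"] if groups is not None else []) + ["status", "fired_rules"]
    return out[order]


class DuplicateWellCaller:
    """Rule-based classifier over duplicate-well qPCR tables.

    A scikit-learn-style estimator whose ``predict`` maps a long well
    table (two rows per sample) to per-sample POSITIVE / NEGATIVE /
    INVALID calls.  There is nothing to fit — the rules are fixed by
    the cutoff set — but ``fit`` is provided so the object composes
    with sklearn pipelines and ``get_params``/``set_params`` work for
    model selection over algorithms.

    Parameters
    ----------
    algorithm : {"balancing", "one_half", "two_thirds"}, default "balancing"
    include_alx4 : bool, default True
        False re-runs the assay as if the mALX4 channel were absent.
    cutoffs : CutoffSet or None
        Override the algorithm's preset.
    """

    def __init__(
        self,
        algorithm: str = "balancing",
        include_alx4: bool = True,
        cutoffs: CutoffSet | None = None,
    ):
        self.algorithm = algorithm
        self.include_alx4 = include_alx4
        self.cutoffs = cutoffs

    def get_params(self, deep: bool = True) -> dict:
        return {
            "algorithm": self.algorithm,
            "include_alx4": self.include_alx4,
            "cutoffs": self.cutoffs,
        }

    def set_params(self, **params) -> "DuplicateWellCaller":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "DuplicateWellCaller":
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        self.cutoffs_ = self.cutoffs or _ALGORITHMS[self.algorithm][1]
        return self

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-sample call table for a long well table ``X``."""
        if not hasattr(self, "cutoffs_"):
            self.fit()
        return call_cohort(
            X,
            algorithm=self.algorithm,
            include_alx4=self.include_alx4,
            cutoffs=self.cutoffs_,
        )
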