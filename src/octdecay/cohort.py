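"""Data model and I/O for longitudinal retinal-layer-thickness cohorts.

The portable contract is a tidy CSV with one row per (scan, layer,
sector): patient ID, eye, group (CRAO or CONTROL), days since symptom
onset, layer name, ETDRS sector, thickness in μm and a QC flag from
upstream segmentation review.  A wide or differently-named layout is
mapped onto this contract through :class:`ColumnSchema`.  The same
validated path also ingests supplementary-style XLSX workbooks.

Analysis happens at the middle-ring level: the mean of the four 3-mm
ETDRS ring quadrants, the sector associated with acute vision that still
contains all inner and outer layers.  Control (contralateral,
non-affected) eyes are stable over the study horizon and conventionally
enter the fits as day-0 baseline points.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .layers import RING3_QUADRANTS, LayerName, Sector

logger = logging.getLogger(__name__)

#: Canonical tidy-CSV column names, in writing order.
CANONICAL_COLUMNS = (
    "patient_id",
    "eye",
    "group",
    "days_since_onset",
    "layer",
    "sector",
    "thickness_um",
    "qc_pass",
)

VALID_EYES = ("OD", "OS")
VALID_GROUPS = ("CRAO", "CONTROL")

THICKNESS_MIN_UM = 0.0
THICKNESS_MAX_UM = 1000.0


class CohortSchemaError(ValueError):
    """A required column is missing or the schema mapping is invalid."""


class RowValidationError(ValueError):
    """One or more rows failed validation; ``errors`` lists offenders."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        preview = "; ".join(self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {preview}{more}")


@dataclass(frozen=True)
class ColumnSchema:
    """Maps column names in an input table onto the canonical roles.

    Defaults are the canonical names, so a canonical file needs no
    schema.  ``sector`` and ``qc`` may be absent from the source: rows
    then default to the middle-ring mean sector and QC pass.
    """

    patient: str = "patient_id"
    eye: str = "eye"
    group: str = "group"
    day: str = "days_since_onset"
    layer: str = "layer"
    thickness: str = "thickness_um"
    sector: str | None = "sector"
    qc: str | None = "qc_pass"


@dataclass(frozen=True)
class EtdrsSectorGrid:
    """Per-layer thickness (μm) by ETDRS sector for one scan.

    All present values must lie in (0, 1000) μm; a ring is either fully
    present (all four quadrants) or treated as absent when aggregating.
    """

    values: Mapping[Sector, float]

    def __post_init__(self) -> None:
        for sector, v in self.values.items():
            if not (THICKNESS_MIN_UM < v < THICKNESS_MAX_UM):
                raise ValueError(
                    f"thickness for {Sector(sector).value} must be in "
                    f"({THICKNESS_MIN_UM}, {THICKNESS_MAX_UM}) μm, got {v}"
                )

    def __getitem__(self, sector: Sector) -> float:
        return self.values[sector]

    def __contains__(self, sector: Sector) -> bool:
        return sector in self.values


def middle_ring_mean(grid: EtdrsSectorGrid) -> float:
    """Arithmetic mean of the four 3-mm-ring quadrants, μm.

    Raises ``ValueError`` naming the missing quadrant(s) when the ring
    is incomplete.
    """
    missing = [q.value for q in RING3_QUADRANTS if q not in grid]
    if missing:
        raise ValueError(f"missing quadrant(s) for 3-mm ring: {', '.join(missing)}")
    return float(np.mean([grid[q] for q in RING3_QUADRANTS]))


@dataclass(frozen=True)
class ScanRecord:
    """One segmented OCT visit of one eye.

    ``layers`` maps each layer to its sector grid; records built from
    already-collapsed data carry a single ``RING3_MEAN`` entry per layer.
    """

    patient_id: str
    eye: str
    group: str
    days_since_onset: float
    layers: Mapping[LayerName, EtdrsSectorGrid]
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.eye not in VALID_EYES:
            raise ValueError(f"eye must be one of {VALID_EYES}, got {self.eye!r}")
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {VALID_GROUPS}, got {self.group!r}")
        if self.days_since_onset < 0:
            raise ValueError(
                f"days_since_onset must be >= 0, got {self.days_since_onset}"
            )

    @classmethod
    def from_middle_ring(
        cls,
        patient_id: str,
        eye: str,
        group: str,
        days_since_onset: float,
        thickness_by_layer: Mapping[LayerName, float],
        qc_pass: bool = True,
    ) -> "ScanRecord":
        layers = {
            LayerName(l): EtdrsSectorGrid({Sector.RING3_MEAN: float(v)})
            for l, v in thickness_by_layer.items()
        }
        return cls(patient_id, eye, group, float(days_since_onset), layers, qc_pass)


@dataclass
class Cohort:
    """A validated longitudinal cohort in tidy long form.

    ``df`` has exactly the canonical columns; one row per (scan, layer,
    sector), unique on (patient_id, eye, days_since_onset, layer,
    sector).
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise CohortSchemaError(f"cohort frame missing column(s): {missing}")
        self.df = self.df.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
        key = ["patient_id", "eye", "days_since_onset", "layer", "sector"]
        dup = self.df.duplicated(subset=key)
        if dup.any():
            offenders = self.df.loc[dup, key].head(5).to_dict("records")
            raise RowValidationError(
                [f"duplicate observation {o}" for o in offenders]
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_scans(self) -> int:
        return len(
            self.df[["patient_id", "eye", "days_since_onset"]].drop_duplicates()
        )

    def equals(self, other: "Cohort") -> bool:
        a = self.df.sort_values(list(CANONICAL_COLUMNS)).reset_index(drop=True)
        b = other.df.sort_values(list(CANONICAL_COLUMNS)).reset_index(drop=True)
        return a.equals(b)

    @classmethod
    def from_records(
        cls, records: Iterable[ScanRecord], provenance: str = ""
    ) -> "Cohort":
        rows = []
        for r in records:
            for layer, grid in r.layers.items():
                for sector, v in grid.values.items():
                    rows.append(
                        (
                            r.patient_id,
                            r.eye,
                            r.group,
                            r.days_since_onset,
                            LayerName(layer).value,
                            Sector(sector).value,
                            v,
                            r.qc_pass,
                        )
                    )
        df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        return cls(df, provenance=provenance)


def _validate_frame(raw: pd.DataFrame, schema: ColumnSchema, source: str) -> pd.DataFrame:
    required = {
        "patient_id": schema.patient,
        "eye": schema.eye,
        "group": schema.group,
        "days_since_onset": schema.day,
        "layer": schema.layer,
        "thickness_um": schema.thickness,
    }
    missing = [col for col in required.values() if col not in raw.columns]
    if missing:
        raise CohortSchemaError(
            f"{source}: missing required column(s): {', '.join(missing)}"
        )

    df = pd.DataFrame({role: raw[col] for role, col in required.items()})
    if schema.sector is not None and schema.sector in raw.columns:
        df["sector"] = raw[schema.sector]
    else:
        df["sector"] = Sector.RING3_MEAN.value
    if schema.qc is not None and schema.qc in raw.columns:
        df["qc_pass"] = raw[schema.qc]
    else:
        df["qc_pass"] = True

    errors: list[str] = []
    # header is line 1, first data row line 2
    lines = df.index.to_numpy() + 2

    def check(mask: np.ndarray, msg: str) -> None:
        for ln in lines[np.asarray(mask)][:50]:
            errors.append(f"line {ln}: {msg}")

    df["patient_id"] = df["patient_id"].astype(str)
    df["eye"] = df["eye"].astype(str).str.strip().str.upper()
    check(~df["eye"].isin(VALID_EYES).to_numpy(), f"eye not in {VALID_EYES}")
    df["group"] = df["group"].astype(str).str.strip().str.upper()
    check(~df["group"].isin(VALID_GROUPS).to_numpy(), f"group not in {VALID_GROUPS}")

    day = pd.to_numeric(df["days_since_onset"], errors="coerce")
    check(day.isna().to_numpy(), "non-numeric days_since_onset")
    check((day < 0).fillna(False).to_numpy(), "negative days_since_onset")
    df["days_since_onset"] = day.astype(float)

    thick = pd.to_numeric(df["thickness_um"], errors="coerce")
    check(thick.isna().to_numpy(), "non-numeric thickness")
    bad = ~((thick > THICKNESS_MIN_UM) & (thick < THICKNESS_MAX_UM))
    check(bad.fillna(False).to_numpy() & ~thick.isna().to_numpy(),
          f"thickness outside ({THICKNESS_MIN_UM}, {THICKNESS_MAX_UM}) μm")
    df["thickness_um"] = thick.astype(float)

    for col, parser in (("layer", LayerName.parse), ("sector", Sector.parse)):
        parsed = []
        for ln, v in zip(lines, df[col]):
            try:
                parsed.append(parser(v).value)
            except ValueError as e:
                errors.append(f"line {ln}: {e}")
                parsed.append(None)
        df[col] = parsed

    qc = df["qc_pass"]
    if qc.dtype != bool:
        as_str = qc.astype(str).str.strip().str.lower()
        truthy = as_str.isin(("true", "1", "yes"))
        falsy = as_str.isin(("false", "0", "no"))
        check((~truthy & ~falsy).to_numpy(), "qc_pass not interpretable as boolean")
        df["qc_pass"] = truthy
    if errors:
        raise RowValidationError(errors)
    return df


def read_cohort_table(
    source, schema: ColumnSchema | None = None, provenance: str | None = None
) -> Cohort:
    """Read a tidy delimited-text cohort table into a validated Cohort.

    ``source`` is a path or text stream of a comma-separated, UTF-8 file
    with a header row.  Malformed rows are reported with line numbers.
    """
    schema = schema or ColumnSchema()
    name = source if isinstance(source, str) else getattr(source, "name", "<stream>")
    raw = pd.read_csv(source, float_precision="round_trip")
    df = _validate_frame(raw, schema, str(name))
    return Cohort(df, provenance=provenance if provenance is not None else str(name))


def read_cohort_workbook(
    path: str,
    schema: ColumnSchema | None = None,
    sheet: int | str = 0,
    provenance: str | None = None,
) -> Cohort:
    """Read a supplementary-style XLSX workbook through the same schema path."""
    schema = schema or ColumnSchema()
    raw = pd.read_excel(path, sheet_name=sheet)
    df = _validate_frame(raw, schema, str(path))
    return Cohort(df, provenance=provenance if provenance is not None else str(path))


def write_cohort_table(cohort: Cohort, dest) -> None:
    """Write the canonical tidy CSV; read → write → read is the identity."""
    # %.17g round-trips any IEEE double exactly
    cohort.df.to_csv(dest, index=False, float_format="%.17g")


def cohort_round_trip(cohort: Cohort) -> Cohort:
    """Write to an in-memory buffer and read back (round-trip identity check)."""
    buf = io.StringIO()
    write_cohort_table(cohort, buf)
    buf.seek(0)
    return read_cohort_table(buf, provenance=cohort.provenance)


def collapse_to_middle_ring(cohort: Cohort) -> Cohort:
    """Collapse quadrant-level rows to one RING3_MEAN row per (scan, layer).

    Rows already at ``RING3_MEAN`` pass through unchanged.  A (scan,
    layer) with some but not all four 3-mm quadrants raises a
    ``ValueError`` naming the missing quadrant(s).
    """
    df = cohort.df
    mean_rows = df[df["sector"] == Sector.RING3_MEAN.value]
    quad_rows = df[df["sector"].isin([q.value for q in RING3_QUADRANTS])]

    collapsed = []
    key = ["patient_id", "eye", "group", "days_since_onset", "layer", "qc_pass"]
    for keys, sub in quad_rows.groupby(key, sort=False):
        grid = EtdrsSectorGrid(
            {Sector(s): t for s, t in zip(sub["sector"], sub["thickness_um"])}
        )
        try:
            m = middle_ring_mean(grid)
        except ValueError as e:
            pid, eye, _, day = keys[0], keys[1], keys[2], keys[3]
            raise ValueError(
                f"scan ({pid}, {eye}, day {day}), layer {keys[4]}: {e}"
            ) from None
        collapsed.append((*keys[:5], Sector.RING3_MEAN.value, m, keys[5]))

    if not collapsed:
        merged = mean_rows.reset_index(drop=True)
    else:
        out = pd.DataFrame(
            collapsed,
            columns=["patient_id", "eye", "group", "days_since_onset", "layer",
                     "sector", "thickness_um", "qc_pass"],
        )
        frames = [f for f in (mean_rows, out) if not f.empty]
        merged = pd.concat(frames, ignore_index=True)
    return Cohort(merged[list(CANONICAL_COLUMNS)], provenance=cohort.provenance)


@dataclass
class ExclusionLog:
    """Record of QC exclusions applied to a cohort."""

    removed: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def apply_exclusions(cohort: Cohort) -> tuple[Cohort, ExclusionLog]:
    """Drop scans flagged ``qc_pass = False`` (poor layer segmentation).

    Exclusion is per (patient, eye, day) scan; the log lists each removed
    scan.  Idempotent.  Removing everything returns an empty cohort with
    a prominent warning in the log.
    """
    log = ExclusionLog()
    df = cohort.df
    failed = df[~df["qc_pass"]]
    for _, row in (
        failed[["patient_id", "eye", "days_since_onset"]].drop_duplicates().iterrows()
    ):
        log.removed.append(
            {
                "patient_id": row["patient_id"],
                "eye": row["eye"],
                "days_since_onset": float(row["days_since_onset"]),
            }
        )
    kept = df[df["qc_pass"]].reset_index(drop=True)
    if len(kept) == 0 and len(df) > 0:
        log.warnings.append(
            "all records excluded by QC; downstream fits are impossible"
        )
        logger.warning("apply_exclusions: all %d records excluded", len(df))
    return Cohort(kept, provenance=cohort.provenance), log


def baseline_from_controls(
    cohort: Cohort, layer: LayerName
) -> list[tuple[float, float]]:
    """Day-0 baseline points from control eyes for ``layer``.

    Returns one ``(0.0, thickness)`` point per control eye at the
    middle-ring level; these are pooled with the CRAO-eye points before
    fitting.  Control eyes missing the layer are skipped and logged; an
    empty control group yields an empty list with a warning.
    """
    layer = LayerName(layer)
    df = collapse_to_middle_ring(cohort).df
    controls = df[df["group"] == "CONTROL"]
    if controls.empty:
        logger.warning(
            "baseline_from_controls: no control eyes; fit proceeds on CRAO points alone"
        )
        return []
    points: list[tuple[float, float]] = []
    for (pid, eye), sub in controls.groupby(["patient_id", "eye"], sort=False):
        vals = sub.loc[sub["layer"] == layer.value, "thickness_um"]
        if vals.empty:
            logger.info(
                "baseline_from_controls: control eye (%s, %s) has no %s value; skipped",
                pid, eye, layer.value,
            )
            continue
        points.append((0.0, float(vals.mean())))
    return points


def control_summary(cohort: Cohort) -> pd.DataFrame:
    """Per-layer mean, SD (n−1 denominator) and n over control eyes.

    SD is NaN (undefined) for layers observed in a single control eye.
    """
    df = collapse_to_middle_ring(cohort).df
    controls = df[df["group"] == "CONTROL"]
    per_eye = (
        controls.groupby(["layer", "patient_id", "eye"], sort=False)["thickness_um"]
        .mean()
        .reset_index()
    )
    out = (
        per_eye.groupby("layer")["thickness_um"]
        .agg(mean_um="mean", sd_um=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    out.loc[out["n"] < 2, "sd_um"] = np.nan
    return out
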