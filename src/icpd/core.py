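"""Domain model and CSV I/O for intra-crystalline AAR measurements.

The unit of observation is an *analysis*: one chromatographic run of one
fraction (FAA or THAA) of one dated coral subsample, reporting a D/L value
and a concentration for each amino acid. Analyses are grouped into a
:class:`Dataset` together with per-core metadata (collection date, site).

Conventions
-----------
* The internal time axis is *age in years before collection*, so that D/L is
  non-decreasing in age; calendar years appear only in input/output.
* Missing amino acids in a row are recorded as absent, not as zero: a zero
  concentration is a physical claim, absence is an analytical one.
* D/L values above ``DL_MAX`` (1.1) are rejected at read time — racemization
  equilibrates near D/L = 1, so larger values indicate a data error.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Amino acid codes analysed routinely by RP-HPLC in IcPD work. Asx and Glx
#: are composite codes (acid + amide forms deaminate during preparative
#: hydrolysis and are reported together).
AMINO_ACIDS: tuple[str, ...] = (
    "Asx", "Glx", "Ser", "Ala", "Gly", "Val", "Phe", "Leu", "Ile", "Arg",
)
COMPOSITE_CODES = frozenset({"Asx", "Glx"})

FRACTIONS: tuple[str, str] = ("FAA", "THAA")

#: D/L values above this are rejected at read time.
DL_MAX = 1.1


class DatasetError(ValueError):
    """One or more rows violated a hard invariant; carries row diagnostics."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "%d invalid row(s):\n" % len(errors) + "\n".join(errors)
        )


class MetadataError(KeyError):
    """A core code could not be resolved against the core metadata table."""


class UndefinedMetricError(ValueError):
    """A derived metric (e.g. %FAA) is undefined for the given inputs."""


class PercentFreeWarning(UserWarning):
    """%FAA exceeded 100 — physically impossible, marks a compromised run."""


@dataclass
class Analysis:
    """One analytical measurement event (one fraction of one subsample)."""

    analysis_id: str
    core_code: str
    assigned_year: float
    replicate_id: str
    fraction: str
    dl: dict[str, float] = field(default_factory=dict)
    conc: dict[str, float] = field(default_factory=dict)
    exclusion_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValueError(
                f"fraction must be one of {FRACTIONS}, got {self.fraction!r}"
            )

    @property
    def subsample_key(self) -> tuple[str, float]:
        """Key identifying the physical subsample this analysis came from."""
        return (self.core_code, self.assigned_year)

    def copy(self) -> "Analysis":
        return Analysis(
            self.analysis_id, self.core_code, self.assigned_year,
            self.replicate_id, self.fraction,
            dict(self.dl), dict(self.conc), set(self.exclusion_flags),
        )


@dataclass
class CoreMeta:
    """Per-core collection and site metadata."""

    core_code: str
    collection_date: dt.date
    latitude: float = float("nan")
    longitude: float = float("nan")
    mean_annual_sst: float = float("nan")
    seasonal_range: float = float("nan")
    shelf_position: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.collection_date, str):
            self.collection_date = dt.date.fromisoformat(self.collection_date)
        sst = self.mean_annual_sst
        if np.isfinite(sst) and not (15.0 < sst < 35.0):
            raise ValueError(
                f"mean_annual_sst for {self.core_code} must lie in (15, 35) "
                f"degC, got {sst}"
            )


@dataclass
class Dataset:
    """A collection of analyses plus per-core metadata."""

    analyses: list[Analysis]
    cores: dict[str, CoreMeta]

    def validate(self) -> None:
        for a in self.analyses:
            if a.core_code not in self.cores:
                raise MetadataError(
                    f"analysis {a.analysis_id}: unknown core code "
                    f"{a.core_code!r}"
                )
            if sample_age(a, self.cores[a.core_code]) < 0:
                raise DatasetError([
                    f"analysis {a.analysis_id}: assigned_year "
                    f"{a.assigned_year} postdates collection"
                ])

    def __len__(self) -> int:
        return len(self.analyses)

    def get(self, analysis_id: str) -> Analysis:
        for a in self.analyses:
            if a.analysis_id == analysis_id:
                return a
        raise KeyError(analysis_id)

    def subset(self, fraction: str | None = None,
               core_code: str | None = None) -> list[Analysis]:
        out = self.analyses
        if fraction is not None:
            out = [a for a in out if a.fraction == fraction]
        if core_code is not None:
            out = [a for a in out if a.core_code == core_code]
        return out

    def copy(self) -> "Dataset":
        return Dataset([a.copy() for a in self.analyses], dict(self.cores))

    def to_frame(self) -> pd.DataFrame:
        """Wide per-analysis table (one row per analysis)."""
        rows = []
        for a in self.analyses:
            row: dict[str, object] = {
                "analysis_id": a.analysis_id,
                "core_code": a.core_code,
                "assigned_year": a.assigned_year,
                "replicate_id": a.replicate_id,
                "fraction": a.fraction,
                "exclusion_flags": ";".join(sorted(a.exclusion_flags)),
            }
            for aa in AMINO_ACIDS:
                if aa in a.dl:
                    row[f"{aa}_dl"] = a.dl[aa]
                if aa in a.conc:
                    row[f"{aa}_conc"] = a.conc[aa]
            rows.append(row)
        cols = ["analysis_id", "core_code", "assigned_year", "replicate_id",
                "fraction", "exclusion_flags"]
        for aa in AMINO_ACIDS:
            cols += [f"{aa}_dl", f"{aa}_conc"]
        frame = pd.DataFrame(rows)
        return frame.reindex(columns=[c for c in cols if c in frame.columns])


def percent_free(faa_conc: float, thaa_conc: float) -> float:
    """%FAA: share of an amino acid's total pool already in the free form.

    ``100 * faa_conc / thaa_conc``. THAA is the total hydrolysable pool, so
    the free fraction cannot physically exceed it; values > 100 are returned
    but a :class:`PercentFreeWarning` is issued, marking a compromised
    measurement.
    """
    if thaa_conc == 0:
        raise UndefinedMetricError("%FAA undefined: THAA concentration is 0")
    if thaa_conc < 0 or faa_conc < 0:
        raise ValueError("concentrations must be non-negative")
    value = 100.0 * faa_conc / thaa_conc
    if value > 100.0:
        warnings.warn(
            f"%FAA = {value:.1f} exceeds 100: FAA cannot exceed the total "
            "pool; measurement is compromised",
            PercentFreeWarning, stacklevel=2,
        )
    return value


def sample_age(analysis: Analysis, meta: CoreMeta) -> float:
    """Age of a subsample in years before collection.

    Whole calendar years: collection year minus assigned year; the month of
    collection is ignored. Fractional assigned years (sub-annual sampling)
    give fractional ages; rounding happens only at reporting.
    """
    age = meta.collection_date.year - analysis.assigned_year
    if age < 0:
        raise ValueError(
            f"analysis {analysis.analysis_id}: assigned year "
            f"{analysis.assigned_year} is after collection "
            f"({meta.collection_date.year})"
        )
    if float(age).is_integer():
        return int(age)
    return float(age)


# ---------------------------------------------------------------------------
# CSV I/O
#
# Analysis table: one row per analysis, columns
#   analysis_id, core_code, assigned_year, replicate_id, fraction,
#   <AA>_dl, <AA>_conc ...           (missing cells = absent measurements)
# Core table: core_code, collection_date (ISO), latitude, longitude,
#   mean_annual_sst, seasonal_range, shelf_position
# Both are UTF-8 comma-separated with a mandatory header row and '.' decimal;
# lines starting with '#' are provenance comments.
# ---------------------------------------------------------------------------

def read_core_table(path) -> dict[str, CoreMeta]:
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    cores = {}
    for _, row in frame.iterrows():
        code = str(row["core_code"])
        cores[code] = CoreMeta(
            core_code=code,
            collection_date=str(row["collection_date"]),
            latitude=float(row.get("latitude", np.nan)),
            longitude=float(row.get("longitude", np.nan)),
            mean_annual_sst=float(row.get("mean_annual_sst", np.nan)),
            seasonal_range=float(row.get("seasonal_range", np.nan)),
            shelf_position=str(row.get("shelf_position", "")),
        )
    return cores


def write_core_table(cores: dict[str, CoreMeta], path,
                     header_comment: str | None = None) -> None:
    rows = [{
        "core_code": m.core_code,
        "collection_date": m.collection_date.isoformat(),
        "latitude": m.latitude,
        "longitude": m.longitude,
        "mean_annual_sst": m.mean_annual_sst,
        "seasonal_range": m.seasonal_range,
        "shelf_position": m.shelf_position,
    } for m in cores.values()]
    _write_csv(pd.DataFrame(rows), path, header_comment)


def read_dataset(path, cores: dict[str, CoreMeta] | str | None = None,
                 schema: dict[str, str] | None = None) -> Dataset:
    """Read an analysis CSV into a validated :class:`Dataset`.

    Parameters
    ----------
    path : file path of the analysis table.
    cores : core-metadata mapping, or path to a core table CSV.
    schema : optional renaming of the required columns, mapping canonical
        names (``core_code``, ``assigned_year``, ``replicate_id``,
        ``fraction``, ``analysis_id``) to the file's column names.

    Rows violating hard invariants (negative or >1.1 D/L, negative
    concentration, unknown fraction, age < 0) are rejected with row-numbered
    diagnostics via :class:`DatasetError`, never silently dropped.
    """
    if isinstance(cores, (str, bytes)) or hasattr(cores, "read"):
        cores = read_core_table(cores)
    if cores is None:
        raise MetadataError("core metadata is required to read a dataset")
    colmap = {k: k for k in
              ("analysis_id", "core_code", "assigned_year", "replicate_id",
               "fraction", "exclusion_flags")}
    if schema:
        colmap.update(schema)

    frame = pd.read_csv(path, comment="#", float_precision="round_trip",
                        dtype={colmap["core_code"]: str,
                               colmap["replicate_id"]: str})
    errors: list[str] = []
    analyses: list[Analysis] = []
    for idx, row in frame.iterrows():
        rowno = int(idx) + 2  # 1-based + header line
        try:
            core_code = str(row[colmap["core_code"]])
            if core_code not in cores:
                raise MetadataError(
                    f"row {rowno}: unknown core code {core_code!r}"
                )
            year = float(row[colmap["assigned_year"]])
            fraction = str(row[colmap["fraction"]])
            rep = str(row[colmap["replicate_id"]])
            aid_col = colmap["analysis_id"]
            aid = (str(row[aid_col]) if aid_col in frame.columns
                   and pd.notna(row[aid_col]) else f"row{rowno}")
            dl: dict[str, float] = {}
            conc: dict[str, float] = {}
            for aa in AMINO_ACIDS:
                c = f"{aa}_dl"
                if c in frame.columns and pd.notna(row[c]):
                    v = _parse_cell(row[c], rowno, c)
                    if v < 0 or v > DL_MAX:
                        raise ValueError(
                            f"row {rowno}, cell {c}: D/L value {v} outside "
                            f"[0, {DL_MAX}]"
                        )
                    dl[aa] = v
                c = f"{aa}_conc"
                if c in frame.columns and pd.notna(row[c]):
                    v = _parse_cell(row[c], rowno, c)
                    if v < 0:
                        raise ValueError(
                            f"row {rowno}, cell {c}: negative concentration "
                            f"{v}"
                        )
                    conc[aa] = v
            flags: set[str] = set()
            fcol = colmap["exclusion_flags"]
            if fcol in frame.columns and pd.notna(row[fcol]) and row[fcol]:
                flags = set(str(row[fcol]).split(";"))
            a = Analysis(aid, core_code, year, rep, fraction, dl, conc, flags)
            if sample_age(a, cores[core_code]) < 0:  # pragma: no cover
                raise ValueError(f"row {rowno}: negative age")
            analyses.append(a)
        except MetadataError:
            raise
        except (ValueError, KeyError) as exc:
            errors.append(str(exc) if str(exc).startswith("row")
                          else f"row {rowno}: {exc}")
    if errors:
        raise DatasetError(errors)
    ds = Dataset(analyses, dict(cores))
    ds.validate()
    return ds


def write_dataset(dataset: Dataset, path,
                  header_comment: str | None = None) -> None:
    """Write the analysis table; round-trips losslessly via `read_dataset`."""
    _write_csv(dataset.to_frame(), path, header_comment)


def _parse_cell(value, rowno: int, col: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"row {rowno}, cell {col}: unparseable value {value!r}"
        ) from None


def _write_csv(frame: pd.DataFrame, path,
               header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        # .17g guarantees a lossless float round trip
        frame.to_csv(fh, index=False,
                     float_format=lambda v: format(v, ".17g"))
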