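"""Readers and writers for the formats a tree-ring climate analysis touches.

Supported on-disk formats:

* Tucson/RWL decadal ring-width files (the community measurement format),
  auto-detecting 0.01 mm vs 0.001 mm precision from the 999 / -9999 stop
  marker.  Widths are held internally in **mm** as the single unit of record.
* Daily climate tables as CSV with columns ``date, tmin, tmean, precip``.
* Newick phylogenies (via dendropy), validated for unique tips and positive
  branch lengths.
* Flat key/value YAML run configuration, echoed into output headers.

All readers validate and *reject* malformed input rather than repairing it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RingSeries",
    "DailyClimate",
    "PhyloTree",
    "RwlParseError",
    "SchemaError",
    "read_rwl",
    "write_rwl",
    "read_daily_climate",
    "write_daily_climate",
    "read_newick",
    "write_newick",
    "read_config",
    "write_config",
    "write_table",
    "read_table",
]


class RwlParseError(ValueError):
    """Raised for structurally invalid Tucson/RWL content."""


class SchemaError(ValueError):
    """Raised when a tabular input violates its declared schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RingSeries:
    """One core's (or tree's) calendar-dated annual ring widths in mm.

    Years are strictly consecutive; a missing (locally absent) ring is an
    explicit 0.0 entry, never a gap.  ``to_pith`` marks that the innermost
    ring is the tree's first growth year, so cumulative sums of ``trw`` are
    true stem radii.
    """

    series_id: str
    years: np.ndarray
    trw: np.ndarray
    species_code: str = ""
    tree_id: str = ""
    to_pith: bool = True

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.trw = np.asarray(self.trw, dtype=float)
        if self.years.ndim != 1 or self.years.shape != self.trw.shape:
            raise ValueError(f"{self.series_id}: years and trw must be 1-D and equal length")
        if len(self.years) < 2:
            raise ValueError(f"{self.series_id}: a ring series needs at least 2 rings")
        if not np.all(np.diff(self.years) == 1):
            raise ValueError(
                f"{self.series_id}: years must be strictly consecutive "
                "(encode missing rings as width 0)"
            )
        if not np.all(np.isfinite(self.trw)) or np.any(self.trw < 0):
            raise ValueError(f"{self.series_id}: ring widths must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.years)

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])


@dataclass
class DailyClimate:
    """Daily station record: date, minimum/mean temperature (degC), precip (mm)."""

    frame: pd.DataFrame

    REQUIRED = ("date", "tmin", "tmean", "precip")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"daily climate table missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["date"] = pd.to_datetime(df["date"])
        if df["date"].duplicated().any():
            dup = df.loc[df["date"].duplicated(), "date"].iloc[0]
            raise SchemaError(f"duplicate date in daily climate: {dup.date()}")
        if not df["date"].is_monotonic_increasing:
            raise SchemaError("daily climate dates must be strictly increasing")
        for col in ("tmin", "tmean", "precip"):
            if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
                raise SchemaError(f"non-finite value in daily climate column {col!r}")
        if (df["precip"] < 0).any():
            d = df.loc[df["precip"] < 0, "date"].iloc[0]
            raise SchemaError(f"negative precipitation on {d.date()}")
        bad = df["tmin"] > df["tmean"]
        if bad.any():
            d = df.loc[bad, "date"].iloc[0]
            raise SchemaError(f"tmin exceeds tmean on {d.date()}")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class PhyloTree:
    """A rooted phylogeny with species codes at the tips and positive branch lengths."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            seen, dups = set(), set()
            for lab in labels:
                (dups if lab in seen else seen).add(lab)
            raise ValueError(f"duplicate tip label(s): {', '.join(sorted(dups))}")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:  # root edge may be absent
                continue
            if edge.length is None:
                raise ValueError("tree has an edge with no branch length")
            if edge.length <= 0:
                raise ValueError(f"non-positive branch length {edge.length}")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def drop_tip(self, label: str) -> "PhyloTree":
        """Return a new tree with one tip (e.g. a designated outgroup) pruned."""
        if label not in self.tip_labels:
            raise ValueError(f"tip {label!r} not in tree")
        clone = self.tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label != label]
        clone.retain_taxa(taxa)
        clone.purge_taxon_namespace()
        return PhyloTree(clone)


# ---------------------------------------------------------------------------
# Tucson / RWL
# ---------------------------------------------------------------------------

_STOP_MARKERS = {"999": 0.01, "-9999": 0.001}


def read_rwl(
    path: str | Path,
    units_hint: float | None = None,
    species_from_id: int | None = 4,
) -> list[RingSeries]:
    """Read a Tucson/RWL decadal ring-width file.

    Parameters
    ----------
    path
        RWL file; rows are ``<series id> <decade year> <values...>`` with up
        to ten values per row and a stop marker (999 or -9999) after the
        last ring.
    units_hint
        Measurement precision in mm (0.01 or 0.001).  When ``None`` the
        precision is inferred per series from its stop marker.
    species_from_id
        If set, the first this-many characters of the series id are taken
        as the species code (the common ``SSSSTTC`` id convention); pass
        ``None`` to leave species codes empty.
    """
    path = Path(path)
    chunks: dict[str, list[tuple[int, int, list[str]]]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split()
        if len(parts) < 3:
            raise RwlParseError(f"{path.name}:{lineno}: expected id, decade year and values")
        sid = parts[0]
        try:
            decade = int(parts[1])
        except ValueError as exc:
            raise RwlParseError(f"{path.name}:{lineno}: bad decade year {parts[1]!r}") from exc
        chunks.setdefault(sid, []).append((lineno, decade, parts[2:]))
        if sid not in order:
            order.append(sid)

    out: list[RingSeries] = []
    for sid in order:
        rows = chunks[sid]
        values: list[int] = []
        years: list[int] = []
        stop_precision: float | None = None
        expected_year: int | None = None
        for lineno, decade, toks in rows:
            if expected_year is not None and decade != expected_year:
                raise RwlParseError(
                    f"{path.name}:{lineno}: series {sid}: decade row starts at {decade} "
                    f"but {expected_year} values have been read so far"
                )
            year = decade
            decade_end = (decade // 10 + 1) * 10
            for tok in toks:
                if tok in _STOP_MARKERS:
                    stop_precision = _STOP_MARKERS[tok]
                    break
                try:
                    val = int(tok)
                except ValueError as exc:
                    raise RwlParseError(
                        f"{path.name}:{lineno}: series {sid}: unparseable value {tok!r}"
                    ) from exc
                values.append(val)
                years.append(year)
                year += 1
            if stop_precision is not None:
                break
            if year > decade_end:
                raise RwlParseError(
                    f"{path.name}:{lineno}: series {sid}: decade row overruns the "
                    f"decade boundary (runs to year {year - 1}, limit {decade_end - 1})"
                )
            expected_year = year
        if stop_precision is None and units_hint is None:
            raise RwlParseError(f"{path.name}: series {sid}: no stop marker (999/-9999) found")
        precision = units_hint if units_hint is not None else stop_precision
        if precision not in (0.01, 0.001):
            raise RwlParseError(f"{path.name}: series {sid}: unknown precision {precision!r}")
        trw = np.asarray(values, dtype=float) * precision
        species = sid[:species_from_id] if species_from_id else ""
        out.append(
            RingSeries(
                series_id=sid,
                years=np.asarray(years),
                trw=trw,
                species_code=species,
                tree_id=sid,
            )
        )
    return out


def write_rwl(series: Iterable[RingSeries], path: str | Path, precision: float = 0.01) -> None:
    """Write series to Tucson/RWL decadal format at the given precision (mm)."""
    if precision == 0.01:
        stop = "999"
    elif precision == 0.001:
        stop = "-9999"
    else:
        raise ValueError("precision must be 0.01 or 0.001 mm")
    lines: list[str] = []
    for s in series:
        ints = np.rint(s.trw / precision).astype(int)
        year = s.first_year
        i = 0
        while i < len(ints):
            decade_end = (year // 10 + 1) * 10
            n = min(decade_end - year, len(ints) - i)
            vals = " ".join(f"{v:5d}" for v in ints[i : i + n])
            lines.append(f"{s.series_id:<8s}{year:5d} {vals}")
            i += n
            year += n
        lines[-1] += f" {stop}"
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Daily climate CSV
# ---------------------------------------------------------------------------

def read_daily_climate(path: str | Path) -> DailyClimate:
    """Read and validate a daily climate CSV (``date,tmin,tmean,precip``)."""
    df = pd.read_csv(path, comment="#")
    return DailyClimate(df)


def write_daily_climate(daily: DailyClimate, path: str | Path) -> None:
    df = daily.frame.copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> PhyloTree:
    """Read a single rooted Newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"invalid Newick file {path}: {exc}") from exc
    return PhyloTree(tree)


def write_newick(ptree: PhyloTree, path: str | Path) -> None:
    ptree.tree.write(path=str(path), schema="newick", unquoted_underscores=True)


# ---------------------------------------------------------------------------
# Config and provenance-stamped tables
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    """Read a flat key/value YAML config document."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, Mapping):
        raise SchemaError("config must be a flat key/value mapping")
    return dict(data)


def write_config(cfg: Mapping, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(cfg), sort_keys=True))


def write_table(df: pd.DataFrame, path: str | Path, header: Mapping | None = None) -> None:
    """Write a CSV with optional ``# key: value`` provenance header lines."""
    with open(path, "w") as fh:
        if header:
            for key, val in header.items():
                fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, skipping header comments."""
    return pd.read_csv(path, comment="#")
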