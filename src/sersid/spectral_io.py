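"""Data model and plain-text I/O for single-point Raman/SERS spectra.

The atomic unit is a :class:`Spectrum` (one wavenumber axis, one intensity
vector, acquisition metadata); a :class:`SpectrumSet` holds an ordered
collection of spectra on one shared axis together with class and batch
labels. Two delimited-text dialects are supported:

* **wide** — first column ``wavenumber_cm-1``, one column per spectrum;
  per-column metadata in ``#``-prefixed header lines
  (``# sample_id=...``, ``# cell_line=...``, ``# batch=...``).
* **long** — columns ``sample_id, cell_line, batch, wavenumber_cm-1,
  intensity``.

The delimiter is a comma by default; ``.tsv``/``.tab`` paths use tabs.
Floats are written with 12 significant digits so that a write/read cycle
round-trips well below 1e-9 relative error. No interpolation
ever happens on read: spectra that do not share an axis are rejected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "ConfusionMatrix",
    "read_spectrum_table",
    "write_spectrum_table",
    "write_confusion_and_metrics",
    "round_half_away",
]

_FLOAT_FMT = "%.12g"
_MIN_CHANNELS = 8

LONG_COLUMNS = ("sample_id", "cell_line", "batch", "wavenumber_cm-1", "intensity")


def _delimiter_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","


@dataclass(frozen=True)
class Spectrum:
    """One spectrum: wavenumber axis (cm^-1), intensities (counts), metadata.

    ``segments`` records contiguous sub-region lengths after region
    cropping (e.g. fingerprint + CH blocks) so that integration never
    bridges the gap between non-adjacent wavenumber regions.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""
    cell_line: str | None = None
    batch: int | None = None
    segments: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)
        if wn.ndim != 1 or it.ndim != 1 or wn.size != it.size:
            raise ValidationError(
                f"spectrum '{self.sample_id}': wavenumbers and intensities must "
                f"be 1-D vectors of equal length (got {wn.shape} vs {it.shape})"
            )
        if wn.size < _MIN_CHANNELS:
            raise ValidationError(
                f"spectrum '{self.sample_id}': needs at least {_MIN_CHANNELS} "
                f"channels, got {wn.size}"
            )
        if not np.all(np.isfinite(wn)):
            raise ValidationError(f"spectrum '{self.sample_id}': non-finite wavenumber")
        if not np.all(np.isfinite(it)):
            raise ValidationError(f"spectrum '{self.sample_id}': non-finite intensity")
        if self.segments is None:
            if not np.all(np.diff(wn) > 0):
                raise ValidationError(
                    f"spectrum '{self.sample_id}': wavenumber axis must be "
                    "strictly increasing"
                )
        else:
            seg = tuple(int(s) for s in self.segments)
            if any(s < 2 for s in seg) or sum(seg) != wn.size:
                raise ValidationError(
                    f"spectrum '{self.sample_id}': segments {seg} inconsistent "
                    f"with axis length {wn.size}"
                )
            for lo, hi in self._segment_bounds(seg):
                if not np.all(np.diff(wn[lo:hi]) > 0):
                    raise ValidationError(
                        f"spectrum '{self.sample_id}': wavenumbers not strictly "
                        "increasing within a segment"
                    )
            object.__setattr__(self, "segments", seg)
        if self.batch is not None and int(self.batch) < 1:
            raise ValidationError(
                f"spectrum '{self.sample_id}': batch index must be >= 1"
            )

    @staticmethod
    def _segment_bounds(segments: Sequence[int]) -> list[tuple[int, int]]:
        bounds, lo = [], 0
        for s in segments:
            bounds.append((lo, lo + s))
            lo += s
        return bounds

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(intensities, dtype=float))


@dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing one wavenumber axis."""

    spectra: list[Spectrum]
    axis: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.spectra = list(self.spectra)
        for s in self.spectra:
            if s.wavenumbers.size != self.axis.size or not np.array_equal(
                s.wavenumbers, self.axis
            ):
                raise ValidationError(
                    f"spectrum '{s.sample_id}' is not on the shared wavenumber "
                    "axis (no silent interpolation is performed)"
                )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, idx: int) -> Spectrum:
        return self.spectra[idx]

    @property
    def class_labels(self) -> list[str]:
        """Sorted distinct cell-line labels present in the set."""
        return sorted({s.cell_line for s in self.spectra if s.cell_line is not None})

    @property
    def batches(self) -> list[int]:
        return sorted({s.batch for s in self.spectra if s.batch is not None})

    def labels(self) -> np.ndarray:
        return np.array([s.cell_line for s in self.spectra], dtype=object)

    def to_matrix(self) -> np.ndarray:
        """Stack intensities into an (n_spectra, n_channels) matrix."""
        if not self.spectra:
            return np.empty((0, self.axis.size))
        return np.vstack([s.intensities for s in self.spectra])

    def subset_batches(self, batches: Sequence[int]) -> "SpectrumSet":
        keep = set(int(b) for b in batches)
        return SpectrumSet(
            [s for s in self.spectra if s.batch in keep], self.axis
        )


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K integer counts; rows = true class, columns = predicted class."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        counts = np.asarray(self.counts)
        if counts.shape != (len(labels), len(labels)):
            raise ValidationError(
                f"confusion matrix shape {counts.shape} does not match "
                f"{len(labels)} labels"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValidationError("confusion matrix entries must be integral")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValidationError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "counts", counts)

    @classmethod
    def zeros(cls, labels: Sequence[str]) -> "ConfusionMatrix":
        k = len(labels)
        return cls(tuple(labels), np.zeros((k, k), dtype=np.int64))

    @classmethod
    def from_pairs(
        cls, true: Sequence[str], predicted: Sequence[str], labels: Sequence[str]
    ) -> "ConfusionMatrix":
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(true, predicted, strict=True):
            counts[index[t], index[p]] += 1
        return cls(tuple(labels), counts)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValidationError(
                "cannot add confusion matrices with different label sets: "
                f"{self.labels} vs {other.labels}"
            )
        return ConfusionMatrix(self.labels, self.counts + other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties going away from zero (so 89.35 -> 89.4, not 89.3+).

    Reported percentages use this convention; NaN passes through.
    """
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# spectrum tables
# ---------------------------------------------------------------------------

def write_spectrum_table(
    sset: SpectrumSet,
    path: str | Path,
    dialect: str = "long",
    sep: str | None = None,
) -> None:
    """Write a SpectrumSet as a delimited text table (``long`` or ``wide``)."""
    path = Path(path)
    delim = _delimiter_for(path, sep)
    if dialect == "long":
        _write_long(sset, path, delim)
    elif dialect == "wide":
        _write_wide(sset, path, delim)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}; use 'long' or 'wide'")


def read_spectrum_table(
    path: str | Path, dialect: str = "long", sep: str | None = None
) -> SpectrumSet:
    """Read a delimited spectrum table and validate it into a SpectrumSet.

    Long-dialect rows may appear in any wavenumber order; they are sorted
    per spectrum before validation. Spectra on non-identical axes are
    rejected rather than interpolated.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"spectrum table not found: {path}")
    delim = _delimiter_for(path, sep)
    if dialect == "long":
        return _read_long(path, delim)
    if dialect == "wide":
        return _read_wide(path, delim)
    raise ValidationError(f"unknown dialect {dialect!r}; use 'long' or 'wide'")


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def _check_token(token: str, delim: str, what: str) -> str:
    if delim in token or "\n" in token or "\r" in token:
        raise ValidationError(
            f"{what} {token!r} contains the delimiter or a newline and cannot "
            "be written unambiguously"
        )
    return token


def _write_long(sset: SpectrumSet, path: Path, delim: str) -> None:
    n = sset.axis.size
    for s in sset:
        _check_token(s.sample_id, delim, "sample_id")
        if s.cell_line is not None:
            _check_token(s.cell_line, delim, "cell_line")
    df = pd.DataFrame(
        {
            "sample_id": np.repeat([s.sample_id for s in sset], n),
            "cell_line": np.repeat(
                ["" if s.cell_line is None else s.cell_line for s in sset], n
            ),
            "batch": np.repeat(
                ["" if s.batch is None else str(int(s.batch)) for s in sset], n
            ),
            "wavenumber_cm-1": np.tile([_fmt(v) for v in sset.axis], len(sset)),
            "intensity": [
                _fmt(v) for s in sset for v in s.intensities
            ],
        },
        columns=list(LONG_COLUMNS),
    )
    df.to_csv(path, sep=delim, index=False, encoding="utf-8")


def _read_long(path: Path, delim: str) -> SpectrumSet:
    try:
        df = pd.read_csv(
            path, sep=delim, dtype={"sample_id": str, "cell_line": str}, encoding="utf-8"
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected a header row") from None
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df.empty:
        return SpectrumSet([], np.empty(0))
    spectra: list[Spectrum] = []
    axis: np.ndarray | None = None
    # groupby with sort=False preserves order of first appearance
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("wavenumber_cm-1", kind="stable")
        wn = grp["wavenumber_cm-1"].to_numpy(dtype=float)
        cell = grp["cell_line"].iloc[0]
        cell = None if pd.isna(cell) or cell == "" else str(cell)
        batch_raw = grp["batch"].iloc[0]
        batch = None if pd.isna(batch_raw) else int(batch_raw)
        s = Spectrum(
            wavenumbers=wn,
            intensities=grp["intensity"].to_numpy(dtype=float),
            sample_id=str(sid),
            cell_line=cell,
            batch=batch,
        )
        if axis is None:
            axis = s.wavenumbers
        spectra.append(s)
    assert axis is not None
    return SpectrumSet(spectra, axis)


def _write_wide(sset: SpectrumSet, path: Path, delim: str) -> None:
    sids = [_check_token(s.sample_id, delim, "sample_id") for s in sset]
    cells = [
        _check_token("" if s.cell_line is None else s.cell_line, delim, "cell_line")
        for s in sset
    ]
    batches = ["" if s.batch is None else str(int(s.batch)) for s in sset]
    buf = io.StringIO()
    buf.write("# sample_id=" + delim.join(sids) + "\n")
    buf.write("# cell_line=" + delim.join(cells) + "\n")
    buf.write("# batch=" + delim.join(batches) + "\n")
    buf.write(delim.join(["wavenumber_cm-1"] + sids) + "\n")
    for i, wn in enumerate(sset.axis):
        row = [_fmt(wn)] + [_fmt(s.intensities[i]) for s in sset]
        buf.write(delim.join(row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _read_wide(path: Path, delim: str) -> SpectrumSet:
    raw_meta: dict[str, str] = {}
    data_lines: list[str] = []
    header: list[str] | None = None
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].lstrip()  # keep trailing delimiters (empty fields)
            if "=" in body:
                key, _, value = body.partition("=")
                raw_meta[key.strip()] = value.rstrip("\n")
            continue
        if header is None:
            header = line.split(delim)
        else:
            data_lines.append(line)
    if header is None or not header or header[0] != "wavenumber_cm-1":
        raise FormatError(
            f"{path}: wide dialect requires first column 'wavenumber_cm-1'"
        )
    n_spec = len(header) - 1
    meta: dict[str, list[str]] = {}
    for key in ("sample_id", "cell_line", "batch"):
        if key not in raw_meta:
            raise FormatError(f"{path}: missing '# {key}=' metadata header line")
        meta[key] = raw_meta[key].split(delim) if n_spec > 0 else []
        if len(meta[key]) != n_spec:
            raise FormatError(
                f"{path}: metadata line '{key}' lists {len(meta[key])} values "
                f"for {n_spec} spectrum columns"
            )
    if n_spec == 0:
        return SpectrumSet([], np.empty(0))
    try:
        block = np.array(
            [[float(tok) for tok in line.split(delim)] for line in data_lines]
        )
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric value in data block ({exc})") from None
    if block.ndim != 2 or block.shape[1] != n_spec + 1:
        raise FormatError(f"{path}: ragged data block")
    axis = block[:, 0]
    spectra = []
    for j in range(n_spec):
        batch_tok = meta["batch"][j]
        spectra.append(
            Spectrum(
                wavenumbers=axis,
                intensities=block[:, j + 1],
                sample_id=meta["sample_id"][j],
                cell_line=meta["cell_line"][j] or None,
                batch=int(batch_tok) if batch_tok != "" else None,
            )
        )
    return SpectrumSet(spectra, axis)


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

def write_confusion_and_metrics(
    cm: ConfusionMatrix, report, path: str | Path, sep: str | None = None
) -> None:
    """Write summed confusion counts plus per-class metric percentages.

    Emits one delimited file with two sections: the raw counts (rows =
    true class) and the per-class sensitivity / specificity / accuracy
    derived from them, percentages rounded to one decimal with ties away
    from zero. ``report`` must carry the same label order as ``cm``.
    """
    path = Path(path)
    delim = _delimiter_for(path, sep)
    if tuple(report.labels) != cm.labels:
        raise ValidationError(
            f"label mismatch between confusion matrix {cm.labels} and metrics "
            f"report {tuple(report.labels)}"
        )

    def _pct_row(name: str, values) -> str:
        cells = []
        for v in values:
            cells.append("" if not np.isfinite(v) else f"{round_half_away(v):.1f}")
        return delim.join([name] + cells)

    lines = ["# summed confusion matrix (rows = true class, columns = predicted)"]
    lines.append(delim.join(["true\\predicted"] + list(cm.labels)))
    for lab, row in zip(cm.labels, cm.counts):
        lines.append(delim.join([lab] + [str(int(v)) for v in row]))
    lines.append("")
    lines.append("# per-class metrics (%)")
    lines.append(delim.join(["metric"] + list(cm.labels)))
    lines.append(_pct_row("pooled sensitivity", report.pooled_sensitivity))
    lines.append(_pct_row("pooled specificity", report.pooled_specificity))
    lines.append(_pct_row("pooled accuracy", report.pooled_accuracy))
    if report.n_splits > 0:
        lines.append(_pct_row("mean sensitivity", report.mean_sensitivity))
        lines.append(_pct_row("sd sensitivity", report.sd_sensitivity))
        lines.append(_pct_row("mean specificity", report.mean_specificity))
        lines.append(_pct_row("sd specificity", report.sd_specificity))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
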