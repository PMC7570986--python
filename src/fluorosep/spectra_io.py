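"""Reading, validation and pretreatment of replicate emission spectra.

Spectra travel as wide CSV tables (rows = plate wells, one header row of
numeric emission wavelengths in nm) accompanied by a metadata CSV
(``well_id, sample_id, replicate, is_blank, condition``).  Pretreatment
consists of quenching normalization — the formal degree of quenching
Q = (I - I0) / I0 against the mean blank spectrum of the same condition —
and restriction to an inclusive wavelength window (e.g. 430-550 nm to cut
the plate-material artifact peak at 420 nm).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

META_COLUMNS = ["well_id", "sample_id", "replicate", "is_blank", "condition"]

# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class SpectraMatrix:
    """Well x wavelength intensity matrix with per-well metadata.

    Parameters
    ----------
    values : ndarray of shape (n_wells, n_wavelengths)
        Raw fluorescence intensities in arbitrary units.
    wavelengths : ndarray of shape (n_wavelengths,)
        Strictly increasing emission wavelength grid in nm.
    well_meta : DataFrame
        One row per well with columns ``well_id, sample_id, replicate,
        is_blank, condition``, aligned with the rows of ``values``.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    well_meta: pd.DataFrame = field(repr=False)

    #: set True on subclasses holding dimensionless normalized data
    is_normalized = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.well_meta = self.well_meta.reset_index(drop=True)
        _validate_matrix(self)

    # -- convenience -------------------------------------------------------

    @property
    def n_wells(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> list[str]:
        return sorted(self.well_meta["condition"].unique())

    def subset_rows(self, mask: np.ndarray) -> "SpectraMatrix":
        return replace(
            self,
            values=self.values[mask],
            well_meta=self.well_meta.loc[np.asarray(mask)].reset_index(drop=True),
        )

    def split_by_condition(self) -> dict[str, "SpectraMatrix"]:
        """One matrix per measurement condition (fluorophore)."""
        out = {}
        for cond in self.conditions:
            out[cond] = self.subset_rows((self.well_meta["condition"] == cond).to_numpy())
        return out

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=[f"{w:g}" for w in self.wavelengths])
        frame.insert(0, "well_id", self.well_meta["well_id"].to_numpy())
        return frame


@dataclass
class QuenchMatrix(SpectraMatrix):
    """Quenching-degree matrix Q = (I - I0)/I0; dimensionless, blank-referenced."""

    is_normalized = True


def _validate_matrix(m: SpectraMatrix) -> None:
    if m.values.ndim != 2:
        raise ValidationError("intensity matrix must be 2-D (wells x wavelengths)")
    if m.wavelengths.ndim != 1 or len(m.wavelengths) != m.values.shape[1]:
        raise ValidationError(
            f"wavelength grid length {len(m.wavelengths)} does not match "
            f"{m.values.shape[1]} intensity columns"
        )
    if len(m.wavelengths) == 0 or m.values.shape[0] == 0:
        raise ValidationError("empty spectra matrix")
    if not np.all(np.diff(m.wavelengths) > 0):
        raise ValidationError("non-monotone grid: wavelengths must be strictly increasing")
    if not np.all(np.isfinite(m.values)):
        raise ValidationError("non-finite intensity encountered (NaN/inf)")
    missing = [c for c in META_COLUMNS if c not in m.well_meta.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    if len(m.well_meta) != m.values.shape[0]:
        raise ValidationError(
            f"{len(m.well_meta)} metadata rows for {m.values.shape[0]} spectra rows"
        )
    meta = m.well_meta
    dup = meta.duplicated(subset=["condition", "sample_id", "replicate"]) & ~meta["is_blank"]
    if dup.any():
        pairs = meta.loc[dup, ["sample_id", "replicate"]].to_records(index=False).tolist()
        raise ValidationError(f"duplicate (sample, replicate) pairs: {pairs}")
    counts = meta.loc[~meta["is_blank"]].groupby(["condition", "sample_id"]).size()
    thin = counts[counts < 2]
    if len(thin):
        raise ValidationError(
            "samples with fewer than 2 replicate wells: "
            + ", ".join(str(k) for k in thin.index.tolist())
        )


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------


def read_spectra(spectra_path: str | Path, meta_path: str | Path) -> SpectraMatrix:
    """Read a wide spectra CSV and its metadata CSV into a validated matrix.

    The spectra file has ``well_id`` as its first column and numeric
    wavelengths as the remaining column headers; the metadata file carries
    ``well_id, sample_id, replicate, is_blank, condition``.  Rows are
    matched on ``well_id`` and must agree exactly between the two files.
    """
    spectra_path, meta_path = Path(spectra_path), Path(meta_path)
    for p in (spectra_path, meta_path):
        if not p.exists():
            raise ValidationError(f"missing file: {p}")
    wide = pd.read_csv(spectra_path)
    if wide.shape[1] < 2:
        raise ValidationError("spectra file needs a well_id column plus wavelength columns")
    try:
        wavelengths = np.array([float(c) for c in wide.columns[1:]])
    except ValueError as exc:
        raise ValidationError(f"non-numeric wavelength header: {exc}") from exc

    meta = pd.read_csv(meta_path)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    meta = meta[META_COLUMNS].copy()
    meta["is_blank"] = _parse_bool(meta["is_blank"])
    meta["well_id"] = meta["well_id"].astype(str)
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["condition"] = meta["condition"].astype(str)

    well_ids = wide.iloc[:, 0].astype(str)
    if set(well_ids) != set(meta["well_id"]):
        only_s = sorted(set(well_ids) - set(meta["well_id"]))[:5]
        only_m = sorted(set(meta["well_id"]) - set(well_ids))[:5]
        raise ValidationError(
            f"key mismatch between spectra and metadata "
            f"(spectra-only: {only_s}, metadata-only: {only_m})"
        )
    if well_ids.duplicated().any():
        raise ValidationError("duplicate well_id rows in spectra file")
    meta = meta.set_index("well_id").loc[well_ids].reset_index()
    return SpectraMatrix(wide.iloc[:, 1:].to_numpy(float), wavelengths, meta)


def _parse_bool(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    out = col.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        raise ValidationError(f"unparseable is_blank values: {col[out.isna()].tolist()}")
    return out.astype(bool)


def write_spectra(matrix: SpectraMatrix, spectra_path: str | Path,
                  meta_path: str | Path | None = None) -> None:
    """Write the wide CSV dialect back out (6 significant digits, stable)."""
    matrix.to_frame().to_csv(spectra_path, index=False, float_format="%.6g")
    if meta_path is not None:
        matrix.well_meta.to_csv(meta_path, index=False)


# --------------------------------------------------------------------------
# pretreatment
# --------------------------------------------------------------------------


def quench_normalize(spectra: SpectraMatrix) -> QuenchMatrix:
    """Compute the formal degree of quenching Q = (I - I0) / I0.

    I0 is the per-wavelength mean intensity over the wells flagged blank
    within the same condition, so each fluorophore is referenced against
    its own blanks.  Blank rows are preserved (their Q averages to zero at
    every wavelength by construction).  Q is negative where the sample
    quenches emission relative to the blank and positive where it enhances
    it.
    """
    if spectra.is_normalized:
        raise ValidationError("input is already quench-normalized")
    q = np.empty_like(spectra.values)
    meta = spectra.well_meta
    for cond in spectra.conditions:
        in_cond = (meta["condition"] == cond).to_numpy()
        blanks = in_cond & meta["is_blank"].to_numpy()
        if not blanks.any():
            raise ValidationError(f"condition {cond!r} has no blank wells")
        i0 = spectra.values[blanks].mean(axis=0)
        bad = np.flatnonzero(np.abs(i0) < 1e-300)
        if len(bad):
            raise ValidationError(
                f"zero mean blank intensity at wavelength "
                f"{spectra.wavelengths[bad[0]]:g} nm (condition {cond!r})"
            )
        q[in_cond] = (spectra.values[in_cond] - i0) / i0
    return QuenchMatrix(q, spectra.wavelengths.copy(), meta.copy())


def select_window(data: SpectraMatrix, lo_nm: float, hi_nm: float) -> SpectraMatrix:
    """Restrict to wavelengths in the closed interval [lo_nm, hi_nm]."""
    if not lo_nm < hi_nm:
        raise ValidationError(f"window bounds must satisfy lo < hi (got {lo_nm}, {hi_nm})")
    keep = (data.wavelengths >= lo_nm) & (data.wavelengths <= hi_nm)
    if not keep.any():
        raise ValidationError(
            f"empty window: [{lo_nm:g}, {hi_nm:g}] nm does not overlap the grid "
            f"[{data.wavelengths[0]:g}, {data.wavelengths[-1]:g}] nm"
        )
    return dataclasses.replace(
        data, values=data.values[:, keep], wavelengths=data.wavelengths[keep]
    )
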