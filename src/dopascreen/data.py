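"""Domain types, validation, and tabular I/O for screening campaign data.

All concentrations are stored internally in molar.  Larval bioassay doses are
accepted in micromolar at the interface (see :mod:`dopascreen.bioassay`) and
kept in micromolar there, because that is the natural reporting unit for
dose-mortality work; everything receptor-side is molar.

Well addresses follow the 384-well convention: letter row ``A``-``P`` plus a
1-based column ``1``-``24``.  Quadrants of the interleaved 16x24 grid are
indexed by (row parity, column parity), the standard scheme for quadrant
replication of a 384-well plate.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

__all__ = [
    "ROLES",
    "HIT_CLASSES",
    "ValidationError",
    "FormatError",
    "WellMeasurement",
    "CompoundRecord",
    "ScreenDesign",
    "ScreenDataset",
    "RunConfig",
    "parse_well_address",
    "format_well_address",
    "well_quadrant",
    "read_plate_csv",
    "write_plate_csv",
    "write_table",
    "read_table",
    "round_sig",
]

ROW_LETTERS = "ABCDEFGHIJKLMNOP"
N_ROWS, N_COLS = 16, 24

ROLES = frozenset(
    {"background", "max_stim", "antagonist_control", "dopamine_curve", "test", "empty"}
)

#: Closed vocabulary of hit classes used to partition confirmed antagonists,
#: mirroring the mode-of-action grouping of the AaDOP2 campaign summary.
HIT_CLASSES = (
    "dopamine_receptor_antagonist",
    "serotonin_receptor_ligand",
    "histamine_receptor_ligand",
    "machr_ligand",
    "uptake_inhibitor",
    "kinase_modulator",
    "miscellaneous",
    "unknown",
)


class ValidationError(ValueError):
    """A record violated a domain invariant."""


class FormatError(ValueError):
    """A file row could not be parsed in the documented dialect."""


_WELL_RE = re.compile(r"^([A-P])0*([1-9][0-9]?)$")


def parse_well_address(address: str) -> tuple[str, int]:
    """Parse ``"A1"``..``"P24"`` into ``(row_letter, column)``.

    Raises :class:`FormatError` for anything outside the 16x24 grid.
    """
    m = _WELL_RE.match(str(address).strip())
    if not m:
        raise FormatError(f"malformed well address {address!r} (expected A1..P24)")
    row, col = m.group(1), int(m.group(2))
    if not 1 <= col <= N_COLS:
        raise FormatError(f"well address {address!r}: column {col} outside 1..{N_COLS}")
    return row, col


def format_well_address(row: str, col: int) -> str:
    return f"{row}{col}"


def well_quadrant(row: str, col: int) -> int:
    """Quadrant 0-3 of the interleaved 384-well grid: 2*(row parity) + column parity."""
    return 2 * (ROW_LETTERS.index(row) % 2) + (col - 1) % 2


@dataclass(frozen=True)
class WellMeasurement:
    """One well's raw luminescence read together with its experimental role."""

    plate_id: str
    row: str
    col: int
    role: str
    compound_id: Optional[str] = None
    concentration: Optional[float] = None  # molar
    luminescence: float = 0.0  # counts per second

    def __post_init__(self) -> None:
        if self.row not in ROW_LETTERS or not 1 <= self.col <= N_COLS:
            raise ValidationError(f"well ({self.row},{self.col}) outside the 16x24 grid")
        if self.role not in ROLES:
            raise ValidationError(f"unknown well role {self.role!r}")
        if self.luminescence < 0:
            raise ValidationError(
                f"negative luminescence {self.luminescence} in {self.plate_id}:{self.address}"
            )
        if self.concentration is not None and self.concentration < 0:
            raise ValidationError("concentration must be >= 0 (molar)")
        if self.role == "test":
            if not self.compound_id:
                raise ValidationError(f"test well {self.plate_id}:{self.address} lacks compound_id")
            if self.concentration is None:
                raise ValidationError(
                    f"test well {self.plate_id}:{self.address} lacks a concentration"
                )
        if self.role == "background" and self.compound_id:
            raise ValidationError("background wells carry neither compound nor dopamine")

    @property
    def address(self) -> str:
        return format_well_address(self.row, self.col)

    @property
    def quadrant(self) -> int:
        return well_quadrant(self.row, self.col)


@dataclass(frozen=True)
class CompoundRecord:
    """Library annotation for one compound."""

    compound_id: str
    name: str = ""
    hit_class: str = "unknown"
    known_mode: str = ""

    def __post_init__(self) -> None:
        if self.hit_class not in HIT_CLASSES:
            raise ValidationError(
                f"compound {self.compound_id}: hit_class {self.hit_class!r} not in "
                f"the closed vocabulary {sorted(HIT_CLASSES)}"
            )


@dataclass(frozen=True)
class ScreenDesign:
    """Replication design of the primary screen."""

    replicates_per_compound: int = 4
    plates_per_compound: int = 2


@dataclass
class ScreenDataset:
    """A validated collection of plate wells plus compound annotations."""

    wells: list[WellMeasurement]
    compounds: list[CompoundRecord] = field(default_factory=list)
    design: ScreenDesign = field(default_factory=ScreenDesign)

    def validate(self, check_design: bool = False) -> "ScreenDataset":
        seen: set[tuple[str, str, int]] = set()
        for w in self.wells:
            key = (w.plate_id, w.row, w.col)
            if key in seen:
                raise ValidationError(
                    f"duplicate well {w.address} on plate {w.plate_id}"
                )
            seen.add(key)
        ids = [c.compound_id for c in self.compounds]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate compound_id in annotation table")
        if check_design:
            self._check_replication()
        return self

    def _check_replication(self) -> None:
        by_compound: dict[str, list[WellMeasurement]] = {}
        for w in self.wells:
            if w.role == "test":
                by_compound.setdefault(w.compound_id, []).append(w)
        for cid, ws in by_compound.items():
            if len(ws) != self.design.replicates_per_compound:
                raise ValidationError(
                    f"compound {cid}: {len(ws)} test wells, expected "
                    f"{self.design.replicates_per_compound}"
                )
            plates = {w.plate_id for w in ws}
            if len(plates) < 2:
                raise ValidationError(f"compound {cid} confined to a single plate")
            for plate in plates:
                quads = [w.quadrant for w in ws if w.plate_id == plate]
                if len(quads) != len(set(quads)):
                    raise ValidationError(
                        f"compound {cid}: replicate wells share a quadrant on {plate}"
                    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.wells:
            rows.append(
                {
                    "plate_id": w.plate_id,
                    "well": w.address,
                    "role": w.role,
                    "compound_id": w.compound_id or "",
                    "concentration_M": w.concentration,
                    "luminescence_cps": w.luminescence,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "plate_id",
                "well",
                "role",
                "compound_id",
                "concentration_M",
                "luminescence_cps",
            ],
        )

    @property
    def plate_ids(self) -> list[str]:
        out: list[str] = []
        for w in self.wells:
            if w.plate_id not in out:
                out.append(w.plate_id)
        return out


@dataclass
class RunConfig:
    """Campaign-level configuration.

    k_sd
        Hit-threshold multiplier: the acceptance band extends ``k_sd`` control
        standard deviations below the antagonist-control mean inhibition.
    censor_limit
        Potencies at or above this molar concentration are reported as
        right-censored ("lacks intrinsic activity"), default 10 uM.
    """

    k_sd: float = 3.0
    censor_limit: float = 1e-5
    rng_seed: int = 0
    noise_cv: float = 0.10
    plate_effect_sd: float = 0.10

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValidationError("k_sd must be positive")
        if self.censor_limit <= 0:
            raise ValidationError("censor_limit must be positive")
        if not 0 <= self.noise_cv < 1:
            raise ValidationError("noise_cv must be a fraction in [0, 1)")
        if self.plate_effect_sd < 0:
            raise ValidationError("plate_effect_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ValidationError(f"unknown configuration keys: {sorted(extra)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_PLATE_COLUMNS = [
    "plate_id",
    "well",
    "role",
    "compound_id",
    "concentration_M",
    "luminescence_cps",
]


def read_plate_csv(path: str | Path, compounds: Sequence[CompoundRecord] = ()) -> ScreenDataset:
    """Read a plate-read CSV into a validated :class:`ScreenDataset`.

    The dialect is comma-separated UTF-8 with a mandatory header carrying the
    columns ``plate_id, well, role, compound_id, concentration_M,
    luminescence_cps``.  Every data row either yields a typed record or raises
    an error naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    wells: list[WellMeasurement] = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            row, col = parse_well_address(rec.well)
            conc = float(rec.concentration_M) if rec.concentration_M != "" else None
            lum = float(rec.luminescence_cps) if rec.luminescence_cps != "" else 0.0
            wells.append(
                WellMeasurement(
                    plate_id=rec.plate_id,
                    row=row,
                    col=col,
                    role=rec.role,
                    compound_id=rec.compound_id or None,
                    concentration=conc,
                    luminescence=lum,
                )
            )
        except (FormatError, ValidationError, ValueError) as exc:
            raise type(exc)(f"{path} row {i}: {exc}") from None
    return ScreenDataset(wells=wells, compounds=list(compounds)).validate()


def write_plate_csv(dataset: ScreenDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report-column convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def write_table(records, path: str | Path, report_sig: dict[str, int] | None = None) -> None:
    """Write a result table as TSV with a stable column order.

    ``records`` may be a DataFrame or an iterable of dataclass instances.  An
    empty table still gets its header when a DataFrame with columns is passed.
    Columns named in ``report_sig`` get a ``<col>_report`` companion rounded to
    the given number of significant figures; machine columns keep full
    precision.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [asdict(r) for r in records]
        df = pd.DataFrame(rows)
    for col, sig in (report_sig or {}).items():
        if col in df.columns:
            df[f"{col}_report"] = [
                round_sig(v, sig) if pd.notna(v) else v for v in df[col]
            ]
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
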