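"""Reading and writing outline coordinate data.

Two plain-text formats are supported: the TPS landmark format (``LM=``,
coordinate rows, ``ID=``) written by the TpsDig family of digitizers, and a
bare x/y coordinate table in which configurations are separated either by
blank lines or by a fixed per-configuration point count (both dialects are
auto-detected).  Hierarchical sample metadata (locality / plant / segment /
replicate) travels in a sidecar CSV because neither coordinate format can
carry it.

Indexing convention: all user-facing indices (fixed landmark "no. 1", axis
landmark "no. 46") are 1-based, matching morphometric usage.  Internally
every array is 0-based NumPy; the translation happens exactly once, inside
:class:`LandmarkScheme`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OutlineConfiguration",
    "LandmarkScheme",
    "study_scheme",
    "scheme_from_yaml",
    "read_coordinate_table",
    "write_coordinate_table",
    "read_tps",
    "write_tps",
    "read_metadata",
    "reverse_and_relabel_replicate",
    "FormatError",
]


class FormatError(ValueError):
    """A coordinate file violates its format contract."""


@dataclass
class OutlineConfiguration:
    """One digitized outline: ordered 2D points plus identity metadata.

    Points are dimensionless image units; no pixel scaling is applied.
    """

    points: np.ndarray
    segment_id: str = ""
    plant_id: str = ""
    locality: str = ""
    replicate: int = 1
    reflected: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (k, 2), got {pts.shape}")
        if pts.shape[0] < 3:
            raise ValueError("an outline needs at least 3 points")
        dup = np.where((np.diff(pts, axis=0) == 0).all(axis=1))[0]
        if dup.size:
            raise ValueError(
                f"consecutive coincident points at index {dup[0] + 1}: "
                "outline must be a simple ordered curve")
        self.points = pts

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def copy(self, **changes) -> "OutlineConfiguration":
        out = replace(self, **changes)
        if "points" not in changes:
            out.points = self.points.copy()
        return out


@dataclass(frozen=True)
class LandmarkScheme:
    """Symmetry and topology contract for one landmark configuration.

    All constructor arguments are 1-based.  ``pairing`` maps each left-side
    index to its mirror partner on the right; on-axis indices appear in no
    pair.  ``fixed_index`` is the single anatomical landmark that never
    slides.
    """

    n_points: int
    fixed_index: int
    axis_indices: tuple[int, int]
    pairing: Mapping[int, int]
    closed: bool = True

    def __post_init__(self) -> None:
        paired = set()
        for l, r in self.pairing.items():
            paired.update((l, r))
        axis = set(self.axis_indices)
        if paired & axis:
            raise ValueError("axis indices must be unpaired")
        expected = set(range(1, self.n_points + 1)) - axis
        if paired != expected:
            raise ValueError("every non-axis point must appear in exactly one pair")

    # -- 0-based views used internally ------------------------------------
    @property
    def fixed0(self) -> int:
        return self.fixed_index - 1

    @property
    def axis0(self) -> tuple[int, int]:
        return (self.axis_indices[0] - 1, self.axis_indices[1] - 1)

    def swap_permutation(self) -> np.ndarray:
        """0-based permutation sending each index to its mirror partner
        (axis points map to themselves)."""
        perm = np.arange(self.n_points)
        for l, r in self.pairing.items():
            perm[l - 1] = r - 1
            perm[r - 1] = l - 1
        return perm

    @property
    def sliding0(self) -> np.ndarray:
        """0-based indices of points allowed to slide (all but the fixed one)."""
        return np.array([i for i in range(self.n_points) if i != self.fixed0])


def scheme_from_yaml(path) -> LandmarkScheme:
    """Load a landmark scheme from YAML.

    Keys (all indices 1-based): ``n_points``, ``fixed_index``,
    ``axis_indices`` (pair), ``pairing`` (left -> right map), ``closed``.
    A file containing only ``n_points`` gets the standard study pairing
    (mirror pairs i and n+2-i).
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if set(raw) <= {"n_points"}:
        return study_scheme(int(raw.get("n_points", 90)))
    return LandmarkScheme(
        n_points=int(raw["n_points"]),
        fixed_index=int(raw["fixed_index"]),
        axis_indices=tuple(raw["axis_indices"]),
        pairing={int(k): int(v) for k, v in raw["pairing"].items()},
        closed=bool(raw.get("closed", True)),
    )


def study_scheme(n_points: int = 90) -> LandmarkScheme:
    """The closed-outline scheme with one basal fixed landmark.

    Point 1 is the fixed basal landmark, point ``n/2 + 1`` (46 for 90 points)
    sits opposite on the symmetry axis, and points ``i`` and ``n + 2 - i``
    are mirror pairs.
    """
    if n_points % 2 != 0 or n_points < 6:
        raise ValueError("scheme requires an even n_points >= 6")
    top = n_points // 2 + 1
    pairing = {i: n_points + 2 - i for i in range(2, top)}
    return LandmarkScheme(
        n_points=n_points,
        fixed_index=1,
        axis_indices=(1, top),
        pairing=pairing,
        closed=True,
    )


# ---------------------------------------------------------------------------
# coordinate tables
# ---------------------------------------------------------------------------

def _parse_numeric_rows(lines: Iterable[tuple[int, str]]) -> list[tuple[int, float, float]]:
    rows = []
    for lineno, line in lines:
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: expected two columns, got {len(parts)}")
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: malformed numeric token: {line!r}") from exc
        rows.append((lineno, x, y))
    return rows


def read_coordinate_table(
    path,
    metadata_map: pd.DataFrame | None = None,
    n_points: int | None = None,
    scheme: LandmarkScheme | None = None,
) -> list[OutlineConfiguration]:
    """Read a plain x/y coordinate table.

    Configurations are delimited by blank lines; if the file contains no
    blank line, ``n_points`` (or ``scheme.n_points``) is used to split a
    single run of rows into equally sized records.  ``metadata_map`` is a
    frame with columns ``config_index`` (1-based file order), ``locality``,
    ``plant``, ``segment``, ``replicate``.
    """
    path = Path(path)
    if scheme is not None and n_points is None:
        n_points = scheme.n_points

    blocks: list[list[tuple[int, str]]] = [[]]
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                if blocks[-1]:
                    blocks.append([])
                continue
            blocks[-1].append((lineno, line))
    if blocks and not blocks[-1]:
        blocks.pop()

    if len(blocks) == 1 and n_points is not None and len(blocks[0]) > n_points:
        rows = blocks[0]
        if len(rows) % n_points:
            raise FormatError(
                f"{len(rows)} rows are not divisible by k = {n_points}"
            )
        blocks = [rows[i:i + n_points] for i in range(0, len(rows), n_points)]

    configs: list[OutlineConfiguration] = []
    for bi, block in enumerate(blocks):
        rows = _parse_numeric_rows(block)
        pts = np.array([(x, y) for _, x, y in rows])
        if n_points is not None and pts.shape[0] != n_points:
            raise FormatError(
                f"configuration {bi + 1}: {pts.shape[0]} points, expected {n_points}"
            )
        configs.append(OutlineConfiguration(points=pts, segment_id=str(bi + 1)))

    if metadata_map is not None:
        _attach_metadata(configs, metadata_map)
    return configs


def write_coordinate_table(path, configs: Sequence[OutlineConfiguration], precision: int = 10) -> None:
    """Write configurations as blank-line separated x/y rows."""
    with open(path, "w") as fh:
        for i, cfg in enumerate(configs):
            if i:
                fh.write("\n")
            for x, y in cfg.points:
                fh.write(f"{x:.{precision}f} {y:.{precision}f}\n")


def _attach_metadata(configs: list[OutlineConfiguration], meta: pd.DataFrame) -> None:
    required = {"config_index", "locality", "plant", "segment", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"metadata table missing columns: {sorted(missing)}")
    meta = meta.set_index("config_index")
    for i, cfg in enumerate(configs, start=1):
        if i not in meta.index:
            raise FormatError(f"metadata missing for configuration {i}")
        row = meta.loc[i]
        cfg.locality = str(row["locality"])
        cfg.plant_id = str(row["plant"])
        cfg.segment_id = str(row["segment"])
        cfg.replicate = int(row["replicate"])


def read_metadata(path) -> pd.DataFrame:
    """Read the sidecar metadata CSV (config_index, locality, plant,
    segment, replicate)."""
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# TPS format
# ---------------------------------------------------------------------------

def read_tps(path) -> list[OutlineConfiguration]:
    """Read a TPS landmark file.

    Supports ``LM=``, coordinate rows, ``ID=``; a ``SCALE=`` line is ignored
    with a logged warning (coordinates stay dimensionless).  Records without
    an ``ID=`` line receive sequential ids ``1, 2, ...`` by file order.
    """
    path = Path(path)
    configs: list[OutlineConfiguration] = []
    lm_expected: int | None = None
    rows: list[tuple[int, str]] = []
    cfg_id: str | None = None

    def flush(lineno: int) -> None:
        nonlocal lm_expected, rows, cfg_id
        if lm_expected is None:
            return
        parsed = _parse_numeric_rows(rows)
        if len(parsed) != lm_expected:
            raise FormatError(
                f"record ending before line {lineno}: LM={lm_expected} "
                f"but {len(parsed)} coordinate rows"
            )
        pts = np.array([(x, y) for _, x, y in parsed])
        ident = cfg_id if cfg_id is not None else str(len(configs) + 1)
        configs.append(OutlineConfiguration(points=pts, segment_id=ident))
        lm_expected, rows, cfg_id = None, [], None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush(lineno)
                try:
                    lm_expected = int(line[3:])
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: bad LM= count") from exc
            elif upper.startswith("ID="):
                cfg_id = line[3:].strip()
            elif upper.startswith("SCALE="):
                logger.warning("line %d: SCALE= ignored; coordinates kept dimensionless", lineno)
            elif upper.startswith(("IMAGE=", "CURVES=", "POINTS=", "COMMENT=")):
                continue
            else:
                if lm_expected is None:
                    raise FormatError(f"line {lineno}: coordinate row outside a record")
                rows.append((lineno, line))
    flush(-1)
    return configs


def write_tps(path, configs: Sequence[OutlineConfiguration], precision: int = 10) -> None:
    """Write configurations to a TPS file (LM=, rows, ID=)."""
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.n_points}\n")
            for x, y in cfg.points:
                fh.write(f"{x:.{precision}f} {y:.{precision}f}\n")
            fh.write(f"ID={cfg.segment_id or ''}\n")


# ---------------------------------------------------------------------------
# replicate direction correction
# ---------------------------------------------------------------------------

def reverse_and_relabel_replicate(
    config: OutlineConfiguration, scheme: LandmarkScheme
) -> OutlineConfiguration:
    """Reverse the traversal direction of an outline about its fixed landmark.

    A second digitization registered in the opposite direction is brought to
    the dataset convention by keeping the fixed landmark at index 1 and
    reversing the order of all following points.  Applying the operation
    twice is the identity.
    """
    pts = config.points
    k = pts.shape[0]
    if k != scheme.n_points:
        raise ValueError(f"configuration has {k} points, scheme expects {scheme.n_points}")
    f = scheme.fixed0
    rolled = np.roll(pts, -f, axis=0)          # fixed landmark to slot 0
    reversed_ = np.concatenate([rolled[:1], rolled[1:][::-1]], axis=0)
    out = np.roll(reversed_, f, axis=0)        # restore original slot
    return config.copy(points=out)


def write_anova_csv(path, table) -> None:
    """Write an ANOVA table to CSV (effect, df, SS, MS, F, p, R2)."""
    table.to_frame().to_csv(path, index=False)
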