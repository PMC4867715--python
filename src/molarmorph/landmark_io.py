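"""Reading, writing and standardizing 2D landmark configurations.

Data enter the pipeline as TPS files (the format written by tpsDig) or as
wide CSV tables, one row per specimen. Each lower-molar configuration is a
fixed protocol of 15 landmarks: the four main cusp tips (protoconid,
metaconid, hypoconid, entoconid) forming the occlusal polygon, eight points
on the crown outline, and three points on the crests. Before any shape
analysis, configurations are scaled to millimetres and standardized to the
right side; mirroring a left molar also requires remapping the landmark
order so that buccal and lingual landmarks keep their anatomical meaning.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_LANDMARKS = 15

TEETH = ("M1", "M2")
SIDES = ("left", "right")

#: Groves-style subfamilies (8) and Rosenberger-style subfamilies (5).
SUBFAMILIES_G = (
    "Cebinae",
    "Saimiriinae",
    "Callitrichinae",
    "Pitheciinae",
    "Callicebinae",
    "Aotinae",
    "Atelinae",
    "Alouattinae",
)
SUBFAMILIES_R = (
    "Cebinae",
    "Callitrichinae",
    "Pitheciinae",
    "Homunculinae",
    "Atelinae",
)
FAMILIES = ("Cebidae", "Atelidae", "Pitheciidae")

#: Index remapping applied when a configuration is mirrored: buccal and
#: lingual landmarks swap roles (cusp tips 1<->4 and 2<->3, outline points
#: 6<->12, 7<->11 and 8<->10), while the mesial/distal midline points and
#: the crest points (5, 9, 13, 14, 15) stay in place.  1-based pairs.
MIRROR_SWAP_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 4),
    (2, 3),
    (6, 12),
    (7, 11),
    (8, 10),
)


def mirror_permutation(
    swap_pairs: Sequence[tuple[int, int]] = MIRROR_SWAP_PAIRS,
    n_landmarks: int = N_LANDMARKS,
) -> np.ndarray:
    """0-based permutation vector implementing the mirror landmark remap."""
    perm = np.arange(n_landmarks)
    for a, b in swap_pairs:
        perm[a - 1], perm[b - 1] = b - 1, a - 1
    return perm


#: Landmark protocol: (index, type, definition).  Type 2 landmarks are
#: geometric extrema (cusp tips, maxima of curvature); type 3 landmarks are
#: constructed points defined relative to other features.
LANDMARK_SCHEME: tuple[tuple[int, str, str], ...] = (
    (1, "type2", "Tip of the distolingual cusp (entoconid)"),
    (2, "type2", "Tip of the mesiolingual cusp (metaconid)"),
    (3, "type2", "Tip of the mesiobuccal cusp (protoconid)"),
    (4, "type2", "Tip of the distobuccal cusp (hypoconid)"),
    (5, "type3", "Most distal point of the mid mesiodistal line on the crown outline"),
    (6, "type2", "Point of maximum curvature directly below the entoconid"),
    (7, "type3", "Point on the dental crown outline at the lingual groove"),
    (8, "type2", "Point of maximum curvature directly below the metaconid"),
    (9, "type3", "Most mesial point of the mid mesiodistal line on the crown outline"),
    (10, "type2", "Point of maximum curvature directly below the protoconid"),
    (11, "type3", "Point on the dental crown outline at the mesial groove"),
    (12, "type2", "Point of maximum curvature directly below the hypoconid"),
    (13, "type2", "Midpoint between the preentocristid and postmetacristid"),
    (14, "type2", "Lowest point on the protocristid"),
    (15, "type2", "Lowest point on the crista obliqua"),
)


class LandmarkError(ValueError):
    """Malformed landmark data (parse failures, invariant violations)."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's ordered 15-landmark occlusal configuration.

    Coordinates are stored in image units until :func:`apply_scale` converts
    them to millimetres (``scale`` is mm per image unit).
    """

    specimen_id: str
    tooth: str
    side: str
    landmarks: np.ndarray
    scale: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        lm = np.asarray(self.landmarks, dtype=float)
        if lm.shape != (N_LANDMARKS, 2):
            raise LandmarkError(
                f"specimen {self.specimen_id!r}: expected {N_LANDMARKS} 2D "
                f"landmarks, got array of shape {lm.shape}"
            )
        if not np.all(np.isfinite(lm)):
            raise LandmarkError(f"specimen {self.specimen_id!r}: non-finite coordinate")
        if self.tooth not in TEETH:
            raise LandmarkError(f"specimen {self.specimen_id!r}: unknown tooth {self.tooth!r}")
        if self.side not in SIDES:
            raise LandmarkError(f"specimen {self.specimen_id!r}: unknown side {self.side!r}")
        if not self.scale > 0:
            raise LandmarkError(f"specimen {self.specimen_id!r}: scale must be > 0")
        # degenerate digitization: two landmarks digitized on the same pixel
        d = lm[:, None, :] - lm[None, :, :]
        same = (np.abs(d).sum(axis=2) == 0) & ~np.eye(N_LANDMARKS, dtype=bool)
        if same.any():
            i, j = np.argwhere(same)[0]
            raise LandmarkError(
                f"specimen {self.specimen_id!r}: landmarks {i + 1} and {j + 1} coincide"
            )
        object.__setattr__(self, "landmarks", lm)
        lm.setflags(write=False)


@dataclass(frozen=True)
class TaxonomyMap:
    """Specimen → taxon labels at four nested grouping levels.

    Extant specimens must carry a species, genus, both subfamily schemes
    (the 8-subfamily Groves arrangement and the 5-subfamily Rosenberger
    arrangement) and a family. Fossil specimens are flagged and may carry a
    fossil code (F1..F13) instead of extant labels.
    """

    table: pd.DataFrame

    REQUIRED = (
        "specimen_id",
        "species",
        "genus",
        "subfamily_G",
        "subfamily_R",
        "family",
        "fossil_flag",
    )

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise LandmarkError(f"taxonomy table missing columns: {missing}")
        if t["specimen_id"].duplicated().any():
            dup = t.loc[t["specimen_id"].duplicated(), "specimen_id"].tolist()
            raise LandmarkError(f"duplicate specimen_ids in taxonomy: {dup}")
        extant = t[~t["fossil_flag"].astype(bool)]
        for col, domain in (
            ("subfamily_G", SUBFAMILIES_G),
            ("subfamily_R", SUBFAMILIES_R),
            ("family", FAMILIES),
        ):
            bad = set(extant[col]) - set(domain)
            if bad:
                raise LandmarkError(f"unknown {col} labels for extant specimens: {sorted(bad)}")
        for col in ("species", "genus", "subfamily_G", "subfamily_R", "family"):
            if extant[col].isna().any() or (extant[col] == "").any():
                raise LandmarkError(f"extant specimen with empty {col} label")
        object.__setattr__(self, "table", t.set_index("specimen_id", drop=False))

    def labels(self, level: str, specimen_ids: Sequence[str]) -> np.ndarray:
        """Group labels at ``level`` (family/subfamily_G/subfamily_R/genus/species)."""
        return self.table.loc[list(specimen_ids), level].to_numpy()

    def is_fossil(self, specimen_id: str) -> bool:
        return bool(self.table.loc[specimen_id, "fossil_flag"])

    @property
    def specimen_ids(self) -> list[str]:
        return self.table["specimen_id"].tolist()


@dataclass
class ShapeDataset:
    """A validated collection of same-tooth configurations plus taxonomy."""

    configurations: list[LandmarkConfiguration]
    taxonomy: TaxonomyMap
    tooth: str

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def fossil_ids(self) -> list[str]:
        tax = self.taxonomy.table
        return [
            c.specimen_id
            for c in self.configurations
            if c.specimen_id in tax.index and tax.loc[c.specimen_id, "fossil_flag"]
        ]

    @property
    def extant_ids(self) -> list[str]:
        fossil = set(self.fossil_ids)
        return [i for i in self.specimen_ids if i not in fossil]

    def coords(self, specimen_ids: Sequence[str] | None = None) -> np.ndarray:
        """(n, 15, 2) coordinate array in stored order (or the given order)."""
        if specimen_ids is None:
            return np.stack([c.landmarks for c in self.configurations])
        by_id = {c.specimen_id: c for c in self.configurations}
        return np.stack([by_id[i].landmarks for i in specimen_ids])

    def labels(self, level: str, specimen_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.extant_ids if specimen_ids is None else list(specimen_ids)
        return self.taxonomy.labels(level, ids)


# ---------------------------------------------------------------------------
# TPS format
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r"^([A-Za-z]+)\s*=\s*(.*)$")


def read_tps(path: str | Path | io.TextIOBase, tooth: str) -> list[LandmarkConfiguration]:
    """Parse a TPS file into configurations, one per ``LM=`` record.

    Accepts ``LM=``, ``ID=``, ``IMAGE=``, ``SCALE=`` and ``SIDE=`` lines;
    curve/outline blocks are ignored. A record without ``SCALE=`` keeps
    scale 1.0 with a logged warning; a record without ``SIDE=`` defaults to
    right (the study's standardized orientation).

    Raises :class:`LandmarkError` for an empty file, a record whose landmark
    count differs from 15, or a non-numeric coordinate, naming the record.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        name = getattr(path, "name", "<stream>")
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        lines = p.read_text().splitlines()
        name = str(p)

    configs: list[LandmarkConfiguration] = []
    i, record_idx = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _KV_RE.match(line)
        if not m or m.group(1).upper() != "LM":
            raise LandmarkError(f"{name}: unexpected line {i + 1!r}: {line!r} (expected LM=)")
        record_idx += 1
        try:
            n_lm = int(m.group(2))
        except ValueError:
            raise LandmarkError(f"{name}: record {record_idx}: bad LM= value {m.group(2)!r}")
        if n_lm != N_LANDMARKS:
            raise LandmarkError(
                f"{name}: record {record_idx}: LM={n_lm}, expected {N_LANDMARKS}"
            )
        i += 1
        pts = []
        while len(pts) < n_lm:
            if i >= len(lines):
                raise LandmarkError(
                    f"{name}: record {record_idx}: ended after {len(pts)} of {n_lm} landmarks"
                )
            row = lines[i].strip()
            i += 1
            if not row:
                continue
            parts = row.split()
            if len(parts) != 2:
                raise LandmarkError(
                    f"{name}: record {record_idx}: bad coordinate line {row!r}"
                )
            try:
                pts.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise LandmarkError(
                    f"{name}: record {record_idx}: non-numeric coordinate {row!r}"
                )
        # trailing key=value lines for this record
        spec_id, scale, side, source = None, None, "right", ""
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            m = _KV_RE.match(row)
            if not m:
                raise LandmarkError(f"{name}: record {record_idx}: unexpected line {row!r}")
            key = m.group(1).upper()
            if key == "LM":
                break
            i += 1
            val = m.group(2).strip()
            if key == "ID":
                spec_id = val
            elif key == "SCALE":
                try:
                    scale = float(val)
                except ValueError:
                    raise LandmarkError(
                        f"{name}: record {record_idx}: bad SCALE= value {val!r}"
                    )
            elif key == "SIDE":
                side = val.lower()
            elif key in ("IMAGE", "COMMENT"):
                source = val
            elif key in ("CURVES", "POINTS", "OUTLINES"):
                # outline blocks: skip their coordinate payload
                try:
                    n_skip = int(val)
                except ValueError:
                    n_skip = 0
                skipped = 0
                while i < len(lines) and skipped < n_skip:
                    if not _KV_RE.match(lines[i].strip()):
                        skipped += 1
                    i += 1
            # unknown keys are tolerated silently
        if spec_id is None:
            spec_id = f"record_{record_idx}"
        if scale is None:
            logger.warning(
                "%s: record %d (%s): no SCALE= line, assuming 1.0", name, record_idx, spec_id
            )
            scale = 1.0
        configs.append(
            LandmarkConfiguration(
                specimen_id=spec_id,
                tooth=tooth,
                side=side,
                landmarks=np.array(pts),
                scale=scale,
                source=source,
            )
        )
    if not configs:
        raise LandmarkError(f"{name}: no landmark records found")
    return configs


def write_tps(configs: Iterable[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations back to TPS (LM/coords/ID/SIDE/SCALE per record)."""
    out = []
    for c in configs:
        out.append(f"LM={N_LANDMARKS}")
        for x, y in c.landmarks:
            out.append(f"{x:.10g} {y:.10g}")
        if c.source:
            out.append(f"IMAGE={c.source}")
        out.append(f"ID={c.specimen_id}")
        out.append(f"SIDE={c.side}")
        out.append(f"SCALE={c.scale:.10g}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV formats
# ---------------------------------------------------------------------------

def _coord_columns() -> list[str]:
    cols = []
    for k in range(1, N_LANDMARKS + 1):
        cols += [f"x{k}", f"y{k}"]
    return cols


def configurations_to_frame(configs: Iterable[LandmarkConfiguration]) -> pd.DataFrame:
    rows = []
    for c in configs:
        row = {"specimen_id": c.specimen_id, "tooth": c.tooth, "side": c.side, "scale": c.scale}
        for k, (x, y) in enumerate(c.landmarks, start=1):
            row[f"x{k}"], row[f"y{k}"] = x, y
        rows.append(row)
    return pd.DataFrame(rows, columns=["specimen_id", "tooth", "side", "scale"] + _coord_columns())


def read_coordinates_csv(path: str | Path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path)
    needed = ["specimen_id", "tooth", "side", "scale"] + _coord_columns()
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise LandmarkError(f"{path}: coordinate CSV missing columns {missing}")
    configs = []
    for _, row in df.iterrows():
        lm = np.array(
            [[row[f"x{k}"], row[f"y{k}"]] for k in range(1, N_LANDMARKS + 1)], dtype=float
        )
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(row["specimen_id"]),
                tooth=str(row["tooth"]),
                side=str(row["side"]),
                landmarks=lm,
                scale=float(row["scale"]),
            )
        )
    return configs


def write_coordinates_csv(configs: Iterable[LandmarkConfiguration], path: str | Path) -> None:
    configurations_to_frame(configs).to_csv(path, index=False)


def read_taxonomy_csv(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, dtype={"specimen_id": str})
    if "fossil_code" not in df.columns:
        df["fossil_code"] = ""
    df["fossil_flag"] = df["fossil_flag"].astype(bool)
    return TaxonomyMap(df)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize_side(
    c: LandmarkConfiguration,
    swap_pairs: Sequence[tuple[int, int]] = MIRROR_SWAP_PAIRS,
) -> LandmarkConfiguration:
    """Mirror a left-side configuration into right-side orientation.

    Reflects x -> -x, re-centres into the positive quadrant, and remaps the
    landmark order with the buccal<->lingual swap table so landmark k keeps
    its anatomical definition. Right-side input is returned unchanged.
    """
    if c.side == "right":
        return c
    if c.side != "left":
        raise LandmarkError(f"specimen {c.specimen_id!r}: unknown side {c.side!r}")
    lm = c.landmarks.copy()
    lm[:, 0] = -lm[:, 0]
    lm -= lm.min(axis=0)  # back into the positive quadrant
    lm = lm[mirror_permutation(swap_pairs)]
    return replace(c, landmarks=lm, side="right")


def apply_scale(c: LandmarkConfiguration) -> LandmarkConfiguration:
    """Convert coordinates to millimetres; afterwards scale is 1.0 (a no-op twice)."""
    if not c.scale > 0:
        raise LandmarkError(f"specimen {c.specimen_id!r}: scale must be > 0")
    if c.scale == 1.0:
        return c
    return replace(c, landmarks=c.landmarks * c.scale, scale=1.0)


def assemble_dataset(
    configs: Sequence[LandmarkConfiguration],
    taxonomy: TaxonomyMap,
    tooth: str,
) -> ShapeDataset:
    """Validate and bundle configurations with their taxonomy.

    Every extant specimen must appear in the taxonomy; fossils missing from
    the taxonomy are tolerated (flagged rows are appended for them).
    Duplicate specimen ids and mixed teeth are rejected.
    """
    teeth = {c.tooth for c in configs}
    if teeth != {tooth}:
        raise LandmarkError(f"mixed or wrong teeth in dataset: found {sorted(teeth)}, expected {tooth}")
    ids = [c.specimen_id for c in configs]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise LandmarkError(f"duplicate specimen ids: {sorted(dup)}")
    tax = taxonomy.table
    unknown = [i for i in ids if i not in tax.index]
    if unknown:
        raise LandmarkError(
            f"specimens missing from taxonomy (extant specimens must be mapped): {unknown}"
        )
    return ShapeDataset(configurations=list(configs), taxonomy=taxonomy, tooth=tooth)


def standardize_dataset(
    configs: Sequence[LandmarkConfiguration],
    flip_y: bool = False,
) -> list[LandmarkConfiguration]:
    """Scale to mm and side-standardize every configuration.

    ``flip_y`` reflects y before side handling, for images digitized with a
    top-left pixel origin rather than the mathematical y-up convention.
    """
    out = []
    for c in configs:
        if flip_y:
            lm = c.landmarks.copy()
            lm[:, 1] = -lm[:, 1]
            lm -= lm.min(axis=0)
            c = replace(c, landmarks=lm)
        out.append(standardize_side(apply_scale(c)))
    return out
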