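"""Synthetic landmark datasets with the structure the analysis assumes.

The generator emulates the study design end to end: a comparative sample of
extant platyrrhines (61 species in 18 genera, 8 Groves subfamilies, 5
Rosenberger subfamilies, 3 families, with the published per-species
specimen counts), a 15-landmark lower-molar protocol, hierarchical
between-group mean-shape differences, isotropic within-species landmark
noise, a handful of out-of-sample "fossil" configurations, and repeated
digitizations of a specimen panel with small independent error. Each
emitted specimen additionally carries a random similarity transform
(rotation, translation, image scale) and a random side (left specimens are
mirrored with the landmark order remapped), so the reading/standardization
and superimposition stages are exercised exactly as they would be on real
digitizations.

All randomness flows from a single seed through one named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmark_io import (
    MIRROR_SWAP_PAIRS,
    LandmarkConfiguration,
    ShapeDataset,
    TaxonomyMap,
    mirror_permutation,
)
from .shape_pca import ThinPlateSpline

# ---------------------------------------------------------------------------
# Reference taxonomy: genus -> (subfamily_G, subfamily_R, family), and the
# published per-species specimen counts of the comparative sample.
# ---------------------------------------------------------------------------

GENUS_CLASSIFICATION: dict[str, tuple[str, str, str]] = {
    "Cebus": ("Cebinae", "Cebinae", "Cebidae"),
    "Sapajus": ("Cebinae", "Cebinae", "Cebidae"),
    "Saimiri": ("Saimiriinae", "Cebinae", "Cebidae"),
    "Callithrix": ("Callitrichinae", "Callitrichinae", "Cebidae"),
    "Mico": ("Callitrichinae", "Callitrichinae", "Cebidae"),
    "Cebuella": ("Callitrichinae", "Callitrichinae", "Cebidae"),
    "Callimico": ("Callitrichinae", "Callitrichinae", "Cebidae"),
    "Leontopithecus": ("Callitrichinae", "Callitrichinae", "Cebidae"),
    "Saguinus": ("Callitrichinae", "Callitrichinae", "Cebidae"),
    "Aotus": ("Aotinae", "Homunculinae", "Cebidae"),
    "Callicebus": ("Callicebinae", "Homunculinae", "Pitheciidae"),
    "Cacajao": ("Pitheciinae", "Pitheciinae", "Pitheciidae"),
    "Chiropotes": ("Pitheciinae", "Pitheciinae", "Pitheciidae"),
    "Pithecia": ("Pitheciinae", "Pitheciinae", "Pitheciidae"),
    "Lagothrix": ("Atelinae", "Atelinae", "Atelidae"),
    "Brachyteles": ("Atelinae", "Atelinae", "Atelidae"),
    "Ateles": ("Atelinae", "Atelinae", "Atelidae"),
    "Alouatta": ("Alouattinae", "Atelinae", "Atelidae"),
}

#: (genus, species, n_specimens) — the comparative sample composition.
SPECIES_SAMPLE: tuple[tuple[str, str, int], ...] = (
    ("Cebus", "albifrons", 9), ("Cebus", "olivaceus", 6),
    ("Sapajus", "apella", 14), ("Sapajus", "libidinosus", 15),
    ("Sapajus", "nigritus", 15), ("Sapajus", "robustus", 15),
    ("Sapajus", "xanthosternos", 7),
    ("Saimiri", "boliviensis", 17), ("Saimiri", "sciureus", 25),
    ("Saimiri", "ustus", 18), ("Saimiri", "vanzolinii", 8),
    ("Callithrix", "aurita", 11), ("Callithrix", "geoffroyi", 15),
    ("Callithrix", "jacchus", 21), ("Callithrix", "kuhlii", 20),
    ("Callithrix", "penicillata", 14),
    ("Mico", "argentata", 21), ("Mico", "chrysoleuca", 16),
    ("Mico", "emiliae", 6), ("Mico", "humeralifer", 16),
    ("Mico", "melanurus", 8),
    ("Cebuella", "pygmaea", 7),
    ("Callimico", "goeldii", 4),
    ("Leontopithecus", "chrysomelas", 5), ("Leontopithecus", "rosalia", 17),
    ("Saguinus", "fuscicollis", 13), ("Saguinus", "imperator", 10),
    ("Saguinus", "labiatus", 9), ("Saguinus", "midas", 22),
    ("Saguinus", "mystax", 13), ("Saguinus", "niger", 14),
    ("Aotus", "azarae", 4), ("Aotus", "nigriceps", 9),
    ("Aotus", "trivirgatus", 21),
    ("Callicebus", "bernhardi", 5), ("Callicebus", "cupreus", 14),
    ("Callicebus", "hoffmannsi", 12), ("Callicebus", "moloch", 16),
    ("Callicebus", "nigrifrons", 8), ("Callicebus", "personatus", 16),
    ("Cacajao", "calvus", 14), ("Cacajao", "melanocephalus", 9),
    ("Chiropotes", "albinasus", 18), ("Chiropotes", "satanas", 15),
    ("Pithecia", "irrorata", 17), ("Pithecia", "monachus", 7),
    ("Pithecia", "pithecia", 16),
    ("Lagothrix", "cana", 7), ("Lagothrix", "lagotricha", 8),
    ("Brachyteles", "arachnoides", 16), ("Brachyteles", "hypoxanthus", 5),
    ("Ateles", "belzebuth", 2), ("Ateles", "chamek", 15),
    ("Ateles", "marginatus", 20),
    ("Alouatta", "belzebul", 15), ("Alouatta", "caraya", 15),
    ("Alouatta", "discolor", 10), ("Alouatta", "guariba", 5),
    ("Alouatta", "guariba clamitans", 15), ("Alouatta", "nigerrima", 10),
    ("Alouatta", "palliata", 15), ("Alouatta", "seniculus", 15),
    ("Alouatta", "ululata", 7),
)


def reference_taxonomy_counts() -> pd.DataFrame:
    """Per-species sample sizes with the full label hierarchy."""
    rows = []
    for genus, species, n in SPECIES_SAMPLE:
        sg, sr, fam = GENUS_CLASSIFICATION[genus]
        rows.append(
            {"genus": genus, "species": f"{genus} {species}", "n": n,
             "subfamily_G": sg, "subfamily_R": sr, "family": fam}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Template
# ---------------------------------------------------------------------------

def make_template() -> np.ndarray:
    """Idealized right lower-molar landmark configuration (mm).

    Axes: +y mesial, -y distal, +x lingual, -x buccal — the crown is seen
    in occlusal view with the mesial border up. Landmarks 1-4 are the cusp
    tips (entoconid, metaconid, protoconid, hypoconid) forming the occlusal
    polygon, 5-12 run around the crown outline (a simple polygon), 13-15
    mark the crests near the midline. The crown is ~5 mm mesiodistally.
    """
    unit = np.array(
        [
            [+0.45, -0.50],   # 1 entoconid (distolingual cusp tip)
            [+0.45, +0.50],   # 2 metaconid (mesiolingual cusp tip)
            [-0.45, +0.50],   # 3 protoconid (mesiobuccal cusp tip)
            [-0.45, -0.50],   # 4 hypoconid (distobuccal cusp tip)
            [0.00, -1.00],    # 5 most distal point of the mid mesiodistal line
            [+0.85, -0.55],   # 6 max curvature below the entoconid
            [+0.90, 0.00],    # 7 outline at the lingual groove
            [+0.85, +0.55],   # 8 max curvature below the metaconid
            [0.00, +1.00],    # 9 most mesial point of the mid mesiodistal line
            [-0.85, +0.55],   # 10 max curvature below the protoconid
            [-0.90, 0.00],    # 11 outline at the buccal (mesial-wall) groove
            [-0.85, -0.55],   # 12 max curvature below the hypoconid
            [+0.20, 0.00],    # 13 midpoint preentocristid/postmetacristid
            [0.00, +0.45],    # 14 lowest point on the protocristid
            [-0.10, -0.20],   # 15 lowest point on the crista obliqua
        ]
    )
    return unit * 2.5  # ~5 mm crown length


OUTLINE_INDICES = (5, 6, 7, 8, 9, 10, 11, 12)  # 1-based, in perimeter order
CUSP_INDICES = (1, 2, 3, 4)


# ---------------------------------------------------------------------------
# Generative specification
# ---------------------------------------------------------------------------

@dataclass
class SynthSpec:
    """Conditions for one synthetic dataset.

    ``group_effect`` (delta, mm) sets the magnitude of between-group mean
    shape offsets; it is attenuated down the hierarchy by
    ``level_weights`` (family, subfamily, genus, species).
    ``within_sigma`` (mm) is the isotropic per-landmark, per-coordinate
    within-species SD; ``digit_sigma`` (mm) the digitization-error SD.
    """

    n_landmarks: int = 15
    taxonomy_counts: pd.DataFrame | None = None  # default: the reference sample
    group_effect: float = 0.15
    within_sigma: float = 0.10
    level_weights: tuple[float, float, float, float] = (1.0, 0.6, 0.35, 0.2)
    digit_sigma: float = 0.02
    n_fossils: int = 6
    fossil_model: str = "centroid_of_group"
    tooth: str = "M1"
    seed: int = 0
    n_displaced_landmarks: int = 5
    image_scale_mm_per_unit: float = 0.02  # emitted coordinates are "pixels"

    def counts(self) -> pd.DataFrame:
        return self.taxonomy_counts if self.taxonomy_counts is not None else reference_taxonomy_counts()


@dataclass
class SynthTruth:
    """Everything needed to score a downstream result exactly."""

    template: np.ndarray
    group_means: dict[str, np.ndarray]        # species -> (k, 2) mean shape
    labels: pd.DataFrame                       # per specimen, all levels
    fossil_recipes: pd.DataFrame               # per fossil: model, source group
    spec: SynthSpec


def _smooth_offset(
    template: np.ndarray, magnitude: float, rng: np.random.Generator, n_controls: int
) -> np.ndarray:
    """Smooth mean-shape displacement: random displacements at a random
    subset of landmarks, thin-plate-spline interpolated to all of them."""
    k = template.shape[0]
    controls = rng.choice(k, size=min(n_controls, k), replace=False)
    disp = rng.normal(size=(len(controls), 2))
    disp *= magnitude / np.sqrt((disp ** 2).mean() * 2)  # per-coordinate RMS = magnitude
    target = template.copy()
    target[controls] += disp
    tps = ThinPlateSpline.fit(template[controls], target[controls])
    return tps(template) - template


def generate(spec: SynthSpec) -> tuple[ShapeDataset, SynthTruth]:
    """Generate a full extant-plus-fossil dataset under ``spec``.

    Group mean shapes are the template plus nested smooth offsets drawn
    once per family, Groves subfamily, genus and species; specimens add
    isotropic landmark noise and a random similarity transform; roughly
    half are emitted as left-side configurations (mirrored, landmark order
    remapped). Fossils are built per ``fossil_model``:

    - ``centroid_of_group``: the exact mean shape of a randomly chosen genus;
    - ``interpolation_between_groups``: midpoint of two genus means;
    - ``offset_novel``: a genus mean plus an extra smooth offset of its own.
    """
    rng = np.random.default_rng(spec.seed)
    template = make_template()
    counts = spec.counts()
    delta = spec.group_effect
    wf, ws, wg, wsp = spec.level_weights

    offsets: dict[tuple[str, str], np.ndarray] = {}

    def level_offset(level: str, name: str, w: float) -> np.ndarray:
        key = (level, name)
        if key not in offsets:
            offsets[key] = (
                _smooth_offset(template, delta * w, rng, spec.n_displaced_landmarks)
                if delta > 0 and w > 0
                else np.zeros_like(template)
            )
        return offsets[key]

    species_means: dict[str, np.ndarray] = {}
    for _, row in counts.iterrows():
        mean = (
            template
            + level_offset("family", row["family"], wf)
            + level_offset("subfamily", row["subfamily_G"], ws)
            + level_offset("genus", row["genus"], wg)
            + level_offset("species", row["species"], wsp)
        )
        species_means[row["species"]] = mean

    perm = mirror_permutation(MIRROR_SWAP_PAIRS)
    configs: list[LandmarkConfiguration] = []
    tax_rows: list[dict] = []
    label_rows: list[dict] = []

    def emit(sid: str, shape_mm: np.ndarray, fossil: bool, fossil_code: str = "") -> None:
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        size_jitter = float(np.exp(rng.normal(0.0, 0.08)))
        shift = rng.uniform(20.0, 400.0, size=2)
        side = "right" if rng.random() < 0.5 else "left"
        xy = shape_mm @ rot.T * size_jitter
        xy = xy / spec.image_scale_mm_per_unit + shift  # into image units
        if side == "left":
            # what a left antimere looks like on the image: reflected, and
            # the digitizer records landmarks in the left-side order
            xy = xy[perm]
            xy = xy * np.array([-1.0, 1.0])
            xy = xy - xy.min(axis=0) + 10.0
        configs.append(
            LandmarkConfiguration(
                specimen_id=sid,
                tooth=spec.tooth,
                side=side,
                landmarks=xy,
                scale=spec.image_scale_mm_per_unit * (1.0 if fossil else 1.0),
                source="synthetic",
            )
        )

    for _, row in counts.iterrows():
        mean = species_means[row["species"]]
        for i in range(int(row["n"])):
            sid = f"{row['species'].replace(' ', '_')}_{i + 1:03d}"
            shape = mean + rng.normal(0.0, spec.within_sigma, size=mean.shape)
            emit(sid, shape, fossil=False)
            tax_rows.append(
                {
                    "specimen_id": sid,
                    "species": row["species"],
                    "genus": row["genus"],
                    "subfamily_G": row["subfamily_G"],
                    "subfamily_R": row["subfamily_R"],
                    "family": row["family"],
                    "fossil_flag": False,
                    "fossil_code": "",
                }
            )
            label_rows.append(tax_rows[-1])

    genera = counts["genus"].unique().tolist()
    fossil_rows = []
    for f in range(spec.n_fossils):
        code = f"F{f + 1}"
        sid = f"fossil_{code}"
        if spec.fossil_model == "centroid_of_group":
            g = genera[int(rng.integers(len(genera)))]
            members = counts[counts["genus"] == g]["species"]
            shape = np.mean([species_means[s] for s in members], axis=0)
            recipe = {"fossil_code": code, "model": spec.fossil_model, "source": g}
        elif spec.fossil_model == "interpolation_between_groups":
            g1, g2 = rng.choice(genera, size=2, replace=False)
            m1 = np.mean([species_means[s] for s in counts[counts["genus"] == g1]["species"]], axis=0)
            m2 = np.mean([species_means[s] for s in counts[counts["genus"] == g2]["species"]], axis=0)
            shape = 0.5 * (m1 + m2)
            recipe = {"fossil_code": code, "model": spec.fossil_model, "source": f"{g1}+{g2}"}
        elif spec.fossil_model == "offset_novel":
            g = genera[int(rng.integers(len(genera)))]
            members = counts[counts["genus"] == g]["species"]
            base = np.mean([species_means[s] for s in members], axis=0)
            shape = base + _smooth_offset(template, delta, rng, spec.n_displaced_landmarks)
            recipe = {"fossil_code": code, "model": spec.fossil_model, "source": g}
        else:
            raise ValueError(f"unknown fossil_model {spec.fossil_model!r}")
        emit(sid, shape, fossil=True, fossil_code=code)
        tax_rows.append(
            {
                "specimen_id": sid, "species": "", "genus": "",
                "subfamily_G": "", "subfamily_R": "", "family": "",
                "fossil_flag": True, "fossil_code": code,
            }
        )
        fossil_rows.append({"specimen_id": sid, **recipe})

    taxonomy = TaxonomyMap(pd.DataFrame(tax_rows))
    dataset = ShapeDataset(configurations=configs, taxonomy=taxonomy, tooth=spec.tooth)
    truth = SynthTruth(
        template=template,
        group_means=species_means,
        labels=pd.DataFrame(label_rows),
        fossil_recipes=pd.DataFrame(
            fossil_rows, columns=["specimen_id", "fossil_code", "model", "source"]
        ),
        spec=spec,
    )
    return dataset, truth


def generate_repetition_study(
    bases: "np.ndarray | list[np.ndarray] | dict[str, np.ndarray]",
    n_rep: int = 9,
    digit_sigma: float = 0.02,
    seed: int = 0,
    n_days: int = 3,
):
    """Repeated digitizations of a specimen panel.

    ``bases`` maps specimen id to its true (k, 2) configuration (a bare
    array or list is keyed automatically); each repetition adds independent
    isotropic noise of SD ``digit_sigma`` per coordinate. Repetitions are
    assigned to ``n_days`` session blocks in order.
    """
    from .error_assessment import RepetitionStudy

    if n_rep < 2:
        raise ValueError("need at least 2 repetitions")
    if isinstance(bases, np.ndarray) and bases.ndim == 2:
        bases = {"specimen_1": bases}
    elif isinstance(bases, (list, tuple)):
        bases = {f"specimen_{i + 1}": b for i, b in enumerate(bases)}
    rng = np.random.default_rng(seed)
    coords = {
        sid: [np.asarray(b, float) + rng.normal(0.0, digit_sigma, size=np.shape(b))
              for _ in range(n_rep)]
        for sid, b in bases.items()
    }
    per_day = int(np.ceil(n_rep / n_days))
    day_labels = [1 + r // per_day for r in range(n_rep)]
    return RepetitionStudy(
        specimen_ids=list(bases), coords=coords, day_labels=day_labels
    )
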