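"""Domain types and CSV I/O for the habitat-selection pipeline.

Field data come in two tables. Habitat observations are 0.5 x 0.5 m quadrats
subdivided into a 5 x 5 grid of cells; each cell is scored for the substrate
categories present plus a concealment ("cover") flag, and per-category
proportions are cell counts over 25. A quadrat is either a random site or the
site where a lizard was found basking, in which case the lizard's sex and
parity mode (egg-laying vs live-bearing) label the observation. Lizard records
carry morphometrics, dorsal/basking/habitat colour, dorsal pattern category
and a genetic admixture membership Q used to classify parity.

Because "cover" overlays the substrate categories, proportions across
categories need not sum to 1; each category is modelled independently.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class HabitatCategory(enum.Enum):
    """The nine modelled habitat categories."""

    ANGIOSPERM = "angiosperm"
    GRASS = "grass"
    LEAF_LITTER = "leaf_litter"
    MOSS = "moss"
    ROCK = "rock"
    WATER = "water"
    WOOD = "wood"
    COVER = "cover"
    BARE_GROUND = "bare_ground"


#: raw field category -> modelled category (None = excluded from modelling)
RAW_CATEGORY_MAP: dict[str, HabitatCategory | None] = {
    **{c.value: c for c in HabitatCategory},
    "bare_soil": HabitatCategory.BARE_GROUND,
    "other": None,
}

#: substrate categories countable from cell contents (cover comes from the flag)
SUBSTRATE_CATEGORIES = [c for c in HabitatCategory if c is not HabitatCategory.COVER]


class Provenance(enum.Enum):
    RANDOM_SITE = "random_site"
    LIZARD_SITE = "lizard_site"


@dataclass(frozen=True)
class QuadratCell:
    """One 3 x 3 cm grid cell: raw categories present plus the cover flag."""

    categories: frozenset[str]
    cover: bool = False

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("cell category set must be non-empty (use 'other')")
        unknown = set(self.categories) - set(RAW_CATEGORY_MAP)
        if unknown:
            raise ValueError(f"unknown raw categories: {sorted(unknown)}")


@dataclass(frozen=True)
class QuadratSample:
    """A 25-cell quadrat with its provenance."""

    site_id: str
    cells: tuple[QuadratCell, ...]
    provenance: Provenance

    def __post_init__(self) -> None:
        if len(self.cells) != 25:
            raise ValueError(f"quadrat must have exactly 25 cells, got {len(self.cells)}")


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"
    NONE = "none"


class Parity(enum.Enum):
    OVIPAROUS = "oviparous"
    VIVIPAROUS = "viviparous"
    NONE = "none"


@dataclass(frozen=True)
class ObservationGroup:
    """Random site, or lizard site labelled with sex and parity mode."""

    kind: str  # "random" | "lizard"
    sex: Sex = Sex.NONE
    parity: Parity = Parity.NONE

    def __post_init__(self) -> None:
        if self.kind not in ("random", "lizard"):
            raise ValueError(f"kind must be 'random' or 'lizard', got {self.kind!r}")
        if self.kind == "random":
            if self.sex is not Sex.NONE or self.parity is not Parity.NONE:
                raise ValueError("random observations carry no sex or parity")
        else:
            if self.sex is Sex.NONE or self.parity is Parity.NONE:
                raise ValueError("lizard observations require sex and parity")


RANDOM_GROUP = ObservationGroup(kind="random")


@dataclass(frozen=True)
class SiteObservation:
    """Per-category proportions for one quadrat, with its group label."""

    site_id: str
    group: ObservationGroup
    proportions: dict[HabitatCategory, float]

    def __post_init__(self) -> None:
        for cat, p in self.proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"proportion for {cat.value} must lie in [0, 1], got {p}"
                )


@dataclass(frozen=True)
class LizardRecord:
    """One individual: morphometrics, colours, pattern and admixture Q.

    ``parity`` here is three-valued ("oviparous", "viviparous", "admixed");
    admixed individuals are excluded from all model fits.
    """

    id: str
    sex: str
    parity: str
    svl_mm: float | None = None
    tl_mm: float | None = None
    mass_g: float | None = None
    dorsal_colour: object | None = None  # ColourHSL
    pattern_anterior: str | None = None
    pattern_posterior: str | None = None
    basking_colour: object | None = None
    habitat_colour: object | None = None
    admixture_q: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.parity not in ("oviparous", "viviparous", "admixed"):
            raise ValueError(f"invalid parity {self.parity!r}")
        for name in ("svl_mm", "tl_mm", "mass_g"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.admixture_q is not None and not 0.0 <= self.admixture_q <= 1.0:
            raise ValueError(f"admixture_q must lie in [0, 1], got {self.admixture_q}")


def compute_proportions(
    quadrat: QuadratSample, group: ObservationGroup | None = None
) -> SiteObservation:
    """Per-category proportions: cells containing the category, over 25.

    ``bare_soil`` cells count toward ``bare_ground``; ``other`` is dropped; the
    cover proportion is the fraction of cells whose cover flag is set. Every
    value is a multiple of 1/25. For a lizard-site quadrat the sex/parity group
    label must be supplied; random sites default to the random group.
    """
    counts = {c: 0 for c in HabitatCategory}
    for cell in quadrat.cells:
        for cat in {RAW_CATEGORY_MAP[raw] for raw in cell.categories}:
            if cat is not None:
                counts[cat] += 1
        if cell.cover:
            counts[HabitatCategory.COVER] += 1
    if group is None:
        if quadrat.provenance is Provenance.LIZARD_SITE:
            raise ValueError("lizard-site quadrats need an explicit sex/parity group")
        group = RANDOM_GROUP
    return SiteObservation(
        site_id=quadrat.site_id,
        group=group,
        proportions={c: counts[c] / 25.0 for c in HabitatCategory},
    )


def classify_parity(q: float, oviparous_is_high: bool = True) -> str:
    """Classify parity from the two-cluster admixture membership Q.

    Q >= 0.9 in the oviparous cluster -> "oviparous"; Q <= 0.1 -> "viviparous";
    anything strictly between -> "admixed" (excluded from fits). The closed
    boundaries classify as pure. ``oviparous_is_high=False`` flips which
    cluster Q indexes.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"Q must lie in [0, 1], got {q}")
    if not oviparous_is_high:
        q = 1.0 - q
    if q >= 0.9:
        return "oviparous"
    if q <= 0.1:
        return "viviparous"
    return "admixed"


# --- CSV I/O ---------------------------------------------------------------

OBSERVATION_COLUMNS = ["site_id", "group_kind", "sex", "parity"] + [
    c.value for c in HabitatCategory
]


class SchemaError(ValueError):
    """A required column is missing or a row fails validation."""


def write_observations(observations: Sequence[SiteObservation], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(OBSERVATION_COLUMNS)
        for obs in observations:
            g = obs.group
            writer.writerow(
                [
                    obs.site_id,
                    g.kind,
                    "" if g.sex is Sex.NONE else g.sex.value,
                    "" if g.parity is Parity.NONE else g.parity.value,
                ]
                + [repr(obs.proportions.get(c, 0.0)) for c in HabitatCategory]
            )


def read_observations(path) -> list[SiteObservation]:
    """Read the observations CSV; malformed rows raise with their line number."""
    out: list[SiteObservation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected a header")
        missing = set(OBSERVATION_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                sex = Sex(row["sex"]) if row["sex"] else Sex.NONE
                parity = Parity(row["parity"]) if row["parity"] else Parity.NONE
                group = ObservationGroup(kind=row["group_kind"], sex=sex, parity=parity)
                props = {}
                for cat in HabitatCategory:
                    raw = row[cat.value]
                    if raw == "":
                        continue
                    p = float(raw)
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(
                            f"column {cat.value!r}: proportion {p} outside [0, 1]"
                        )
                    props[cat] = p
                out.append(
                    SiteObservation(site_id=row["site_id"], group=group, proportions=props)
                )
            except (ValueError, KeyError) as exc:
                raise SchemaError(f"{path}: line {lineno}: {exc}") from exc
    return out


LIZARD_COLUMNS = [
    "id", "sex", "parity", "svl_mm", "tl_mm", "mass_g",
    "dorsal_r", "dorsal_g", "dorsal_b",
    "pattern_anterior", "pattern_posterior",
    "basking_r", "basking_g", "basking_b",
    "habitat_r", "habitat_g", "habitat_b",
    "admixture_q",
]


def _opt_float(value: str) -> float | None:
    return None if value in ("", None) else float(value)


def write_lizards(records: Sequence[LizardRecord], path) -> None:
    """Write lizard records; colours are serialised as RGB channels."""
    from .colour import hsl_to_rgb

    def rgb_cells(colour) -> list[str]:
        if colour is None:
            return ["", "", ""]
        return [repr(v) for v in hsl_to_rgb(colour)]

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LIZARD_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id, r.sex, r.parity,
                    "" if r.svl_mm is None else repr(r.svl_mm),
                    "" if r.tl_mm is None else repr(r.tl_mm),
                    "" if r.mass_g is None else repr(r.mass_g),
                    *rgb_cells(r.dorsal_colour),
                    r.pattern_anterior or "",
                    r.pattern_posterior or "",
                    *rgb_cells(r.basking_colour),
                    *rgb_cells(r.habitat_colour),
                    "" if r.admixture_q is None else repr(r.admixture_q),
                ]
            )


def read_lizards(path, oviparous_is_high: bool = True) -> list[LizardRecord]:
    """Read the lizards CSV. Colours may be given as RGB (``*_r/g/b``) or as
    HSL (``*_h/s/l``) columns; RGB is converted on load. If ``parity`` is
    empty but ``admixture_q`` is present, parity is classified from Q.
    """
    from .colour import ColourHSL, rgb_to_hsl

    out: list[LizardRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected a header")
        fields = set(reader.fieldnames)
        required = {"id", "sex"}
        missing = required - fields
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")

        def colour_of(row, prefix):
            if {f"{prefix}_r", f"{prefix}_g", f"{prefix}_b"} <= fields:
                r, g, b = (row[f"{prefix}_{ch}"] for ch in "rgb")
                if r == "" or g == "" or b == "":
                    return None
                return rgb_to_hsl(float(r), float(g), float(b))
            if {f"{prefix}_h", f"{prefix}_s", f"{prefix}_l"} <= fields:
                h, s, l = (row[f"{prefix}_{ch}"] for ch in "hsl")
                if h == "" or s == "" or l == "":
                    return None
                return ColourHSL(h=float(h), s=float(s), l=float(l))
            return None

        for lineno, row in enumerate(reader, start=2):
            try:
                q = _opt_float(row.get("admixture_q", ""))
                parity = row.get("parity", "")
                if not parity:
                    if q is None:
                        raise ValueError("parity missing and no admixture_q to classify")
                    parity = classify_parity(q, oviparous_is_high=oviparous_is_high)
                out.append(
                    LizardRecord(
                        id=row["id"],
                        sex=row["sex"],
                        parity=parity,
                        svl_mm=_opt_float(row.get("svl_mm", "")),
                        tl_mm=_opt_float(row.get("tl_mm", "")),
                        mass_g=_opt_float(row.get("mass_g", "")),
                        dorsal_colour=colour_of(row, "dorsal"),
                        pattern_anterior=row.get("pattern_anterior") or None,
                        pattern_posterior=row.get("pattern_posterior") or None,
                        basking_colour=colour_of(row, "basking"),
                        habitat_colour=colour_of(row, "habitat"),
                        admixture_q=q,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise SchemaError(f"{path}: line {lineno}: {exc}") from exc
    return out


def read_quadrat_grid(path) -> list[QuadratSample]:
    """Read the optional quadrat grid file (one row per cell).

    Columns: site_id, cell_index (0-24), categories (semicolon-separated raw
    category names), cover_flag (0/1), provenance.
    """
    by_site: dict[str, dict[int, QuadratCell]] = {}
    provenance: dict[str, Provenance] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected a header")
        for lineno, row in enumerate(reader, start=2):
            try:
                cell = QuadratCell(
                    categories=frozenset(
                        c for c in row["categories"].split(";") if c
                    ),
                    cover=row["cover_flag"] == "1",
                )
                idx = int(row["cell_index"])
                if not 0 <= idx <= 24:
                    raise ValueError(f"cell_index {idx} outside 0-24")
                by_site.setdefault(row["site_id"], {})[idx] = cell
                provenance[row["site_id"]] = Provenance(
                    row.get("provenance", "random_site")
                )
            except (ValueError, KeyError) as exc:
                raise SchemaError(f"{path}: line {lineno}: {exc}") from exc
    out = []
    for site_id, cells in by_site.items():
        if len(cells) != 25:
            raise SchemaError(f"{path}: site {site_id!r} has {len(cells)} cells, not 25")
        out.append(
            QuadratSample(
                site_id=site_id,
                cells=tuple(cells[i] for i in range(25)),
                provenance=provenance[site_id],
            )
        )
    return out
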