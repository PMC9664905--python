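"""Build-instruction exporters: Echo picklists and the manual protocol.

Both exports are generated from the same intermediate tables (source-well
map, per-assembly clip volumes, replicate counts), so the acoustic and
manual routes cannot diverge.  Picklist CSVs use the conventional header
``Source Plate Name,Source Well,Destination Plate Name,Destination Well,
Transfer Volume`` with integer volumes in nL, every one an exact multiple
of the droplet quantum.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Literal

import pandas as pd

from . import config
from .build import BasicBuild, clip_multiplicity
from .errors import (ParameterError, PlateOverflowError, QuantizationError,
                     RecipeInfeasibleError)

_PLATE_DIMS = {"384-well": (16, 24), "96-well": (8, 12)}

CLIPS_PLATE = "clips_plate_1"
RESERVOIR_PLATE = "water_buffer_plate_1"
DESTINATION_PLATE = "assembly_plate_1"
WATER_WELL = "A1"
BUFFER_WELL = "A2"


def plate_wells(fmt: str, order: Literal["column-major", "row-major"]) -> list[str]:
    """Well names of a plate format in fill order (A1, B1... for
    column-major)."""
    rows, cols = _PLATE_DIMS[fmt]
    row_names = [chr(ord("A") + r) for r in range(rows)]
    if order == "column-major":
        return [f"{row_names[r]}{c + 1}" for c in range(cols) for r in range(rows)]
    return [f"{row_names[r]}{c + 1}" for r in range(rows) for c in range(cols)]


@dataclasses.dataclass(frozen=True)
class PlateLayout:
    """Source/destination plate geometry and dispensing constraints."""

    source_format: str = "384-well"
    destination_format: str = "96-well"
    order: Literal["column-major", "row-major"] = "column-major"
    dead_volume_nl: int = config.DEFAULT_DEAD_VOLUME_NL
    droplet_quantum_nl: int = config.DEFAULT_DROPLET_QUANTUM_NL

    def __post_init__(self) -> None:
        if self.source_format not in _PLATE_DIMS:
            raise ParameterError(f"unknown plate format {self.source_format!r}")
        if self.destination_format not in _PLATE_DIMS:
            raise ParameterError(f"unknown plate format {self.destination_format!r}")
        if self.droplet_quantum_nl < 1:
            raise ParameterError("droplet quantum must be >= 1 nL")


@dataclasses.dataclass(frozen=True)
class Recipe:
    """Assembly-reaction composition.

    Defaults model a 5 uL reaction with 1/10 volume of 10x assembly buffer
    and 500 nL of each purified clip; water tops up to the total.
    """

    total_volume_nl: int = config.DEFAULT_TOTAL_VOLUME_NL
    clip_volume_nl: int = config.DEFAULT_CLIP_VOLUME_NL
    buffer_fraction: float = config.DEFAULT_BUFFER_FRACTION

    def __post_init__(self) -> None:
        if self.total_volume_nl <= 0 or self.clip_volume_nl <= 0:
            raise ParameterError("volumes must be positive")
        if not (0 <= self.buffer_fraction < 1):
            raise ParameterError("buffer fraction must be in [0, 1)")


@dataclasses.dataclass(frozen=True)
class PicklistRow:
    source_plate: str
    source_well: str
    destination_plate: str
    destination_well: str
    transfer_volume_nl: int


@dataclasses.dataclass(frozen=True)
class Picklist:
    name: str
    rows: tuple[PicklistRow, ...]

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("Source Plate Name,Source Well,Destination Plate Name,"
                  "Destination Well,Transfer Volume\n")
        for r in self.rows:
            buf.write(f"{r.source_plate},{r.source_well},"
                      f"{r.destination_plate},{r.destination_well},"
                      f"{r.transfer_volume_nl}\n")
        return buf.getvalue()


def _quantize(volume: float, quantum: int) -> int:
    """Round to the nearest droplet multiple (half away from zero)."""
    return int((volume + quantum / 2) // quantum) * quantum


def _source_well_map(b: BasicBuild, layout: PlateLayout,
                     capacity: int) -> dict[str, list[str]]:
    """Clip key -> its replicate source wells, assigned in build order."""
    wells = plate_wells(layout.source_format, layout.order)
    cursor = 0
    mapping: dict[str, list[str]] = {}
    for ck, clip in b.clips_data.items():
        reps = clip_multiplicity(clip.total_assemblies, capacity)
        if cursor + reps > len(wells):
            raise PlateOverflowError(
                f"{cursor + reps} clip wells needed but the "
                f"{layout.source_format} source plate has {len(wells)}")
        mapping[ck] = wells[cursor:cursor + reps]
        cursor += reps
    return mapping


def echo_picklists(b: BasicBuild, layout: PlateLayout = PlateLayout(),
                   recipe: Recipe = Recipe(),
                   capacity: int = config.DEFAULT_CLIP_CAPACITY
                   ) -> tuple[Picklist, Picklist]:
    """Generate the clips and water/buffer picklists for a build.

    Each assembly occupies one destination well; its clips are drawn from
    that clip's replicate source wells, rotating to a fresh replicate every
    ``capacity`` assemblies served.  Buffer is rounded to the droplet
    quantum and the remainder reconciled into the water transfer, so clip
    stoichiometry is never rounded and every destination well sums exactly
    to the recipe total.
    """
    q = layout.droplet_quantum_nl
    if recipe.clip_volume_nl % q:
        raise QuantizationError(
            f"clip volume {recipe.clip_volume_nl} nL is not a multiple of "
            f"the {q} nL droplet quantum")
    if recipe.total_volume_nl % q:
        raise QuantizationError(
            f"total volume {recipe.total_volume_nl} nL is not a multiple of "
            f"the {q} nL droplet quantum")
    source_wells = _source_well_map(b, layout, capacity)
    dest_wells = plate_wells(layout.destination_format, layout.order)
    if len(b.assembly_data) > len(dest_wells):
        raise PlateOverflowError(
            f"{len(b.assembly_data)} assemblies but the "
            f"{layout.destination_format} destination plate has "
            f"{len(dest_wells)}")

    buffer_vol = _quantize(recipe.total_volume_nl * recipe.buffer_fraction, q)
    served: dict[str, int] = {ck: 0 for ck in b.clips_data}
    clip_rows: list[PicklistRow] = []
    aux_rows: list[PicklistRow] = []
    for idx, entry in enumerate(b.assembly_data):
        dest = dest_wells[idx]
        clips_total = 0
        for ck in entry.clip_keys:
            replicate = served[ck] // capacity
            served[ck] += 1
            clip_rows.append(PicklistRow(
                CLIPS_PLATE, source_wells[ck][replicate],
                DESTINATION_PLATE, dest, recipe.clip_volume_nl))
            clips_total += recipe.clip_volume_nl
        water_vol = recipe.total_volume_nl - clips_total - buffer_vol
        if water_vol < 0:
            raise RecipeInfeasibleError(
                f"assembly {entry.name!r}: {len(entry.clip_keys)} clips at "
                f"{recipe.clip_volume_nl} nL plus {buffer_vol} nL buffer "
                f"exceed the {recipe.total_volume_nl} nL total")
        if buffer_vol:
            aux_rows.append(PicklistRow(RESERVOIR_PLATE, BUFFER_WELL,
                                        DESTINATION_PLATE, dest, buffer_vol))
        if water_vol:
            aux_rows.append(PicklistRow(RESERVOIR_PLATE, WATER_WELL,
                                        DESTINATION_PLATE, dest, water_vol))
    return (Picklist("echo_clips_1", tuple(clip_rows)),
            Picklist("echo_water_buffer_1", tuple(aux_rows)))


# --- manual instructions ---------------------------------------------------

_PROTOCOL_SECTIONS = ("Clip reactions", "Purification",
                      "Assembly reactions", "Transformation")


@dataclasses.dataclass(frozen=True)
class ManualInstructions:
    """Plain-text protocol plus its machine-readable table twins."""

    text: str
    clips_table: pd.DataFrame
    assemblies_table: pd.DataFrame

    def clips_csv(self) -> str:
        return self.clips_table.to_csv(index=False)

    def assemblies_csv(self) -> str:
        return self.assemblies_table.to_csv(index=False)


def manual_instructions(b: BasicBuild,
                        capacity: int = config.DEFAULT_CLIP_CAPACITY,
                        reaction_volume_l: float = config.DEFAULT_CLIP_REACTION_VOLUME_L
                        ) -> ManualInstructions:
    """Render the four-section manual protocol for a build.

    The clip table lists, per unique clip, the part key and the mass that
    puts the part at its target concentration in the clip reaction, the
    linker halves flanking the part (the suffix half of its prefix linker
    and the prefix half of its suffix linker) and the physical replicate
    count from the clip capacity.
    """
    clip_records = []
    for ck, clip in b.clips_data.items():
        pre = b.unique_linkers[clip.prefix_linker]
        suf = b.unique_linkers[clip.suffix_linker]
        clip_records.append({
            "clip_key": ck,
            "part_key": clip.part,
            "part_id": b.unique_parts[clip.part].id,
            "part_mass_ng": round(clip.part_mass_ng, 2),
            "prefix_linker": pre.id,
            "prefix_half": pre.suffix_half.half_id,
            "suffix_linker": suf.id,
            "suffix_half": suf.prefix_half.half_id,
            "total_assemblies": clip.total_assemblies,
            "replicates": clip_multiplicity(clip.total_assemblies, capacity),
        })
    clips_table = pd.DataFrame(clip_records)
    assembly_records = [{"assembly_key": e.key, "assembly_name": e.name,
                         "clip_keys": ";".join(e.clip_keys)}
                        for e in b.assembly_data]
    assemblies_table = pd.DataFrame(assembly_records)

    ul = int(reaction_volume_l * 1e6)
    lines: list[str] = ["BASIC assembly build instructions", ""]
    lines += [f"1. {_PROTOCOL_SECTIONS[0]}",
              f"   Set up each clip reaction below in {ul} ul, adding the "
              "stated part mass with the stated prefix and suffix linker "
              "halves; prepare the listed number of replicate reactions.", ""]
    header = (f"   {'clip':<6}{'part':<8}{'mass (ng)':>10}  "
              f"{'prefix half':<16}{'suffix half':<16}{'replicates':>10}")
    lines.append(header)
    for r in clip_records:
        lines.append(f"   {r['clip_key']:<6}{r['part_key']:<8}"
                     f"{r['part_mass_ng']:>10.2f}  {r['prefix_half']:<16}"
                     f"{r['suffix_half']:<16}{r['replicates']:>10}")
    lines += ["", f"2. {_PROTOCOL_SECTIONS[1]}",
              "   Purify every clip reaction with magnetic beads and elute; "
              "each purified clip supports up to "
              f"{capacity} assemblies.", ""]
    lines += [f"3. {_PROTOCOL_SECTIONS[2]}",
              "   Mix the purified clips listed per assembly with assembly "
              "buffer and water, then incubate.", ""]
    for r in assembly_records:
        lines.append(f"   {r['assembly_name']}: {r['clip_keys']}")
    lines += ["", f"4. {_PROTOCOL_SECTIONS[3]}",
              "   Transform each assembly reaction into competent cells and "
              "plate on selective medium.", ""]
    return ManualInstructions("\n".join(lines), clips_table, assemblies_table)
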