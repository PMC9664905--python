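"""Package-wide constants and the run configuration record.

All tunables with a physical meaning live here, in one place, so a build is
reproducible from its echoed :class:`RunConfig` alone.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Any

# --- storage-format flanks -------------------------------------------------
# Integrated prefix (iP) / suffix (iS) sequences of the BASIC single-part
# storage format.  Each carries one BsaI recognition site (GGTCTC on the top
# strand of iP, on the bottom strand of iS) so that clip reactions excise the
# part core.  Overridable wherever they matter; all logic treats them as
# opaque flanks of fixed length.
DEFAULT_IP = "TCTGGTGGGTCTCTGTCC"
DEFAULT_IS = "GGCTCGGGAGACCTATCG"

# BsaI recognition sequence and its reverse complement (the bottom-strand
# appearance of the site).
BSAI_SITE = "GGTCTC"
BSAI_SITE_RC = "GAGACC"

# --- validation thresholds -------------------------------------------------
# Parts with cores shorter than this are lost during magnetic-bead
# purification of linker-ligated clips.
MIN_PART_LENGTH = 100
# Demonstrated single-round capacity: parts + linkers combined.  Exceeding it
# is a warning (ambition), not an error (impossibility).
MAX_ASSEMBLY_ELEMENTS = 14

# --- clip-reaction arithmetic ----------------------------------------------
# One purified clip reaction supports 15-30 downstream assemblies depending
# on workflow; the conservative end is the default.
DEFAULT_CLIP_CAPACITY = 15
# Clip reactions are set up so the part sits at 2.5 nM in a 30 ul reaction.
DEFAULT_CLIP_REACTION_VOLUME_L = 30e-6
DEFAULT_PART_CONCENTRATION_M = 2.5e-9

# Average residue masses (g/mol) of the 2'-deoxynucleoside 5'-monophosphates
# and the water lost per phosphodiester bond.  A linear strand of n residues
# weighs sum(residues) - (n - 1) * WATER_MASS; double-stranded weight sums
# both strands.
DNA_RESIDUE_MASS = {
    "A": 331.2218,
    "C": 307.1971,
    "G": 347.2212,
    "T": 322.2085,
}
WATER_MASS = 18.0153
DNA_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# --- primer / oligo design -------------------------------------------------
# Annealing-region search bounds for iP/iS overhang-PCR primers, and the
# nearest-neighbour Tm model conditions (mirroring Biopython Tm_NN defaults;
# concentrations in nM, salts in mM).
PRIMER_MIN_ANNEAL = 15
PRIMER_MAX_ANNEAL = 36
DEFAULT_TARGET_TM = 60.0
DEFAULT_TM_WINDOW = 5.0
TM_CONDITIONS = {"dnac1": 25.0, "dnac2": 25.0, "Na": 50.0, "Mg": 0.0}

# Adapter oligo length for linker-half annealing (the short oligonucleotide
# annealed to each long oligo to form a half-linker duplex).
DEFAULT_ADAPTER_LENGTH = 12

# --- liquid handling -------------------------------------------------------
# Echo 525-class droplet quantum; all transfer volumes are multiples (nL).
DEFAULT_DROPLET_QUANTUM_NL = 25
# Unrecoverable volume per Echo source well (nL).
DEFAULT_DEAD_VOLUME_NL = 2500
# Default assembly-reaction recipe: 5 uL total, 1/10 volume of 10x assembly
# buffer, 500 nL of each purified clip.
DEFAULT_TOTAL_VOLUME_NL = 5000
DEFAULT_BUFFER_FRACTION = 0.1
DEFAULT_CLIP_VOLUME_NL = 500

BUILD_SCHEMA_VERSION = "0.1"


@dataclasses.dataclass
class RunConfig:
    """Snapshot of every tunable governing a run; echoed into output dirs."""

    ip: str = DEFAULT_IP
    is_: str = DEFAULT_IS
    target_tm: float = DEFAULT_TARGET_TM
    tm_window: float = DEFAULT_TM_WINDOW
    min_part_length: int = MIN_PART_LENGTH
    max_assembly_elements: int = MAX_ASSEMBLY_ELEMENTS
    clip_capacity: int = DEFAULT_CLIP_CAPACITY
    clip_reaction_volume_l: float = DEFAULT_CLIP_REACTION_VOLUME_L
    part_concentration_m: float = DEFAULT_PART_CONCENTRATION_M
    adapter_length: int = DEFAULT_ADAPTER_LENGTH
    droplet_quantum_nl: int = DEFAULT_DROPLET_QUANTUM_NL
    dead_volume_nl: int = DEFAULT_DEAD_VOLUME_NL
    total_volume_nl: int = DEFAULT_TOTAL_VOLUME_NL
    buffer_fraction: float = DEFAULT_BUFFER_FRACTION
    clip_volume_nl: int = DEFAULT_CLIP_VOLUME_NL
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data: dict[str, Any] = json.loads(text)
        return cls(**{k: v for k, v in data.items()
                      if k in {f.name for f in dataclasses.fields(cls)}})
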