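"""Programmatic generators for the worked example and the three case studies.

Sources are reconstructed behaviourally: initial token counts (one token
per template gene, replenished enzyme substrates) are declared in-language
with MARKING, and LacI clearance gets its own base-pace turnover process so
that the three administration schemes separate cleanly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .language_ast import ModuleDecl, parse
from .compiler import CompiledModel, compile_module
from .simulator import StimulusSchedule, Trace

__all__ = [
    "FixtureSpec",
    "water_reaction",
    "bacterial_consortium",
    "rgb_morphogen",
    "plasmid_transfer",
    "all_fixtures",
]


@dataclass
class FixtureSpec:
    name: str
    source: str
    grid_shape: tuple[int, int]
    nstep: int
    stimuli: dict[str, tuple[StimulusSchedule, ...]] = field(default_factory=dict)
    properties: dict[str, Callable[[Trace], bool]] = field(default_factory=dict)

    def module(self) -> ModuleDecl:
        return parse(self.source)

    def model(self) -> CompiledModel:
        return compile_module(self.module())


def water_reaction() -> FixtureSpec:
    """One scope, one reaction with stoichiometry 2 H2 + 1 O2 -> 2 H2O."""
    source = """\
MODULE waterReaction
    TIMESCALE 1
    SCOPE s(0, 0)
        MARKING(4*H2_molecule, 2*O2_molecule)
        PROCESS reaction
            TIMESCALE 1
            CUSTOM_PROCESS(2*H2_molecule + O2_molecule -> 2*H2O_molecule)
"""

    def exhaustion_yields_all_water(trace: Trace) -> bool:
        return trace.series("s", "H2O_molecule").iloc[-1] == 4

    return FixtureSpec(
        name="water_reaction",
        source=source,
        grid_shape=(1, 1),
        nstep=50,
        properties={"exhaustion_yields_all_water": exhaustion_yields_all_water},
    )


def bacterial_consortium() -> FixtureSpec:
    """Producer/sensor pair: LacI-inhibitable AHL synthesis, AHL-induced GFP.

    Producer's main process runs at half the base pace, the sensor's at a
    third; AHL diffuses bidirectionally between the two grid cells.
    """
    source = """\
MODULE bacterialConsortium
    TIMESCALE 1
    SCOPE producer(0, 0)
        MARKING(LuxI_gene)
        PROCESS AHL_production
            TIMESCALE 2
            TRANSCRIPTION(LuxI_gene, LuxI_mRNA, INHIBITORS(LacI_protein))
            TRANSLATION(LuxI_mRNA, LuxI_protein)
            DEGRADATION(LuxI_mRNA)
            DEGRADATION(LuxI_protein)
            CUSTOM_PROCESS( -> SAM_molecule)
            CUSTOM_PROCESS( -> ACP_molecule)
            ENZYMATIC_REACTION(LuxI_protein, SAM_molecule + ACP_molecule -> AHL_molecule)
        PROCESS LacI_turnover
            TIMESCALE 1
            DEGRADATION(LacI_protein)
    SCOPE sensor(1, 0)
        MARKING(GFP_reporter_gene)
        PROCESS GFP_production
            TIMESCALE 3
            TRANSCRIPTION(GFP_reporter_gene, GFP_reporter_mRNA, ACTIVATORS(AHL_molecule))
            TRANSLATION(GFP_reporter_mRNA, 2*GFP_reporter_protein)
            DEGRADATION(GFP_reporter_mRNA)
            DEGRADATION(GFP_reporter_protein)
            DEGRADATION(AHL_molecule)
    DIFFUSION(AHL_molecule, producer <-> sensor)
"""
    stimuli = {
        "noLacI": (),
        "lowLacI": (StimulusSchedule(scope="producer", place="LacI_protein", n=3, r=3),),
        "highLacI": (StimulusSchedule(scope="producer", place="LacI_protein", n=3, r=10),),
    }

    def gfp_produced(trace: Trace) -> bool:
        return trace.series("sensor", "GFP_reporter_protein").max() > 0

    return FixtureSpec(
        name="bacterial_consortium",
        source=source,
        grid_shape=(2, 1),
        nstep=100,
        stimuli=stimuli,
        properties={"gfp_produced": gfp_produced},
    )


def _rgb_sender_processes(define: bool) -> list[str]:
    """A-cell processes: full bodies on first use, bare reuse-by-name after."""
    if not define:
        return [
            "        PROCESS BFP_production",
            "        PROCESS CD19_production",
            "        PROCESS mCherry_production",
        ]
    return [
        "        PROCESS BFP_production",
        "            TIMESCALE 1",
        "            TRANSCRIPTION(BFP_gene, BFP_mRNA)",
        "            TRANSLATION(BFP_mRNA, BFP_protein)",
        "        PROCESS CD19_production",
        "            TIMESCALE 1",
        "            TRANSCRIPTION(CD19_gene, CD19_mRNA)",
        "            TRANSLATION(CD19_mRNA, CD19_lig_protein)",
        "        PROCESS mCherry_production",
        "            TIMESCALE 1",
        "            TRANSCRIPTION(mCherry_gene, mCherry_mRNA, ACTIVATORS(GFPlig_protein))",
        "            TRANSLATION(mCherry_mRNA, mCherry_protein)",
        "            TRANSCRIPTION(Ecad_lo_gene, Ecad_lo_mRNA, ACTIVATORS(GFPlig_protein))",
        "            TRANSLATION(Ecad_lo_mRNA, Ecad_lo_protein)",
    ]


def rgb_morphogen(grid_side: int = 5, delete_gfp_lig: bool = False) -> FixtureSpec:
    """Central receiver (B) cell on a grid of sender (A) cells.

    CD19 on A cells drives GFPlig/Ecad_hi in B over contact channels; the
    GFPlig emitted back induces mCherry/Ecad_lo in B's 8 first-degree
    neighbours only.  ``delete_gfp_lig`` removes GFPlig production in B
    (the knock-out variant: no mCherry anywhere, BFP persists).
    """
    if grid_side < 5 or grid_side % 2 == 0:
        raise ValueError("grid_side must be odd and >= 5")
    center = grid_side // 2
    b_id = f"cellB_{center}_{center}"

    def a_id(x: int, y: int) -> str:
        return f"cellA_{x}_{y}"

    neighbors = [
        (center + dx, center + dy)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        if (dx, dy) != (0, 0)
    ]

    lines = ["MODULE rgbMorphogen", "    TIMESCALE 1"]
    defined = False
    for y in range(grid_side):
        for x in range(grid_side):
            if (x, y) == (center, center):
                lines.append(f"    SCOPE {b_id}({x}, {y})")
                lines.append("        MARKING(GFPlig_gene, Ecad_hi_gene)")
                lines.append("        PROCESS GFPlig_production")
                lines.append("            TIMESCALE 1")
                if not delete_gfp_lig:
                    lines.append(
                        "            TRANSCRIPTION(GFPlig_gene, GFPlig_mRNA,"
                        " ACTIVATORS(CD19_lig_protein))"
                    )
                    lines.append("            TRANSLATION(GFPlig_mRNA, 2*GFPlig_protein)")
                lines.append(
                    "            TRANSCRIPTION(Ecad_hi_gene, Ecad_hi_mRNA,"
                    " ACTIVATORS(CD19_lig_protein))"
                )
                lines.append("            TRANSLATION(Ecad_hi_mRNA, Ecad_hi_protein)")
                for nx, ny in neighbors:
                    lines.append(
                        f"        JUXTACRINE_SIGNAL(receive, CD19_lig_protein, {a_id(nx, ny)})"
                    )
                for nx, ny in neighbors:
                    lines.append(
                        f"        JUXTACRINE_SIGNAL(emit, GFPlig_protein, {a_id(nx, ny)})"
                    )
                continue
            lines.append(f"    SCOPE {a_id(x, y)}({x}, {y})")
            lines.append(
                "        MARKING(BFP_gene, CD19_gene, mCherry_gene, Ecad_lo_gene)"
            )
            lines.extend(_rgb_sender_processes(define=not defined))
            defined = True
            if (x, y) in neighbors:
                lines.append(
                    f"        JUXTACRINE_SIGNAL(emit, CD19_lig_protein, {b_id})"
                )
                lines.append(
                    f"        JUXTACRINE_SIGNAL(receive, GFPlig_protein, {b_id})"
                )
    source = "\n".join(lines) + "\n"

    first_degree = [a_id(x, y) for x, y in neighbors]
    second_degree = [
        a_id(x, y)
        for y in range(grid_side)
        for x in range(grid_side)
        if max(abs(x - center), abs(y - center)) == 2
    ]

    def first_degree_mcherry(trace: Trace) -> bool:
        return all(trace.series(s, "mCherry_protein").iloc[-1] >= 1 for s in first_degree)

    def second_degree_dark(trace: Trace) -> bool:
        return all(trace.series(s, "mCherry_protein").max() == 0 for s in second_degree)

    def bfp_everywhere(trace: Trace) -> bool:
        return all(
            trace.series(s, "BFP_protein").iloc[-1] >= 1
            for s in first_degree + second_degree
        )

    return FixtureSpec(
        name="rgb_morphogen" + ("_noGFPlig" if delete_gfp_lig else ""),
        source=source,
        grid_shape=(grid_side, grid_side),
        nstep=60,
        properties={
            "first_degree_mcherry": first_degree_mcherry,
            "second_degree_dark": second_degree_dark,
            "bfp_everywhere": bfp_everywhere,
        },
    )


def plasmid_transfer() -> FixtureSpec:
    """Donor -> pilus -> transconjugant single-strand plasmid relay."""
    source = """\
MODULE plasmidTransfer
    TIMESCALE 1
    SCOPE donor(0, 0)
        MARKING(Rplasmid_gene)
        PROCESS plasmid_expression
            TIMESCALE 1
            TRANSCRIPTION(Rplasmid_gene, Pilus_mRNA)
            TRANSLATION(Pilus_mRNA, Pilus_protein)
            TRANSCRIPTION(Rplasmid_gene, R_mRNA)
            TRANSLATION(R_mRNA, R_protein)
            DEGRADATION(Pilus_mRNA)
            DEGRADATION(R_mRNA)
        PROCESS strand_synthesis
            TIMESCALE 2
            ENZYMATIC_REACTION(Pilus_protein, Rplasmid_gene -> Rplasmid_gene + ssRplasmid_molecule)
        JUXTACRINE_SIGNAL(emit, ssRplasmid_molecule, pilus)
    SCOPE pilus(1, 0)
        JUXTACRINE_SIGNAL(receive, ssRplasmid_molecule, donor)
        JUXTACRINE_SIGNAL(emit, ssRplasmid_molecule, transconjugant)
    SCOPE transconjugant(2, 0)
        PROCESS plasmid_integration
            TIMESCALE 1
            CUSTOM_PROCESS(ssRplasmid_molecule -> Rplasmid_gene)
            TRANSCRIPTION(Rplasmid_gene, R_mRNA)
            TRANSLATION(R_mRNA, R_protein)
            DEGRADATION(R_mRNA)
        JUXTACRINE_SIGNAL(receive, ssRplasmid_molecule, pilus)
"""
    transfer_channel = "jux_ssRplasmid_molecule_pilus_to_transconjugant"

    def donor_keeps_plasmid(trace: Trace) -> bool:
        return bool((trace.series("donor", "Rplasmid_gene") >= 1).all())

    def transconjugant_starts_empty(trace: Trace) -> bool:
        return trace.series("transconjugant", "Rplasmid_gene").iloc[0] == 0

    def r_protein_after_transfer(trace: Trace) -> bool:
        firings = trace.channel_firings(transfer_channel)
        protein = trace.series("transconjugant", "R_protein")
        nonzero = protein[protein > 0]
        if not firings:
            return nonzero.empty  # no transfer: protein must stay at zero
        if nonzero.empty:
            return True  # transfer happened but expression has not fired yet
        return int(nonzero.index[0]) >= firings[0]

    return FixtureSpec(
        name="plasmid_transfer",
        source=source,
        grid_shape=(3, 1),
        nstep=100,
        properties={
            "donor_keeps_plasmid": donor_keeps_plasmid,
            "transconjugant_starts_empty": transconjugant_starts_empty,
            "r_protein_after_transfer": r_protein_after_transfer,
        },
    )


def all_fixtures() -> list[FixtureSpec]:
    return [water_reaction(), bacterial_consortium(), rgb_morphogen(), plasmid_transfer()]
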