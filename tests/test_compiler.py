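import logging

import pytest

from bisdl.compiler import (
    CompileError,
    assign_instance_names,
    compile_module,
    expand_construct,
    model_manifest,
)
from bisdl.language_ast import parse
from bisdl.nwn_core import ARC_INHIBITOR, ARC_INPUT, ARC_OUTPUT, ARC_READ, structure_signature


def _parse_construct(line: str):
    src = (
        "MODULE m\n    TIMESCALE 1\n    SCOPE s(0, 0)\n"
        f"        PROCESS p\n            TIMESCALE 1\n            {line}\n"
    )
    return parse(src).scopes[0].processes[0].constructs[0]


class TestExpandConstruct:
    def test_complex_formation_template(self):
        construct = _parse_construct(
            "PROTEIN_COMPLEX_FORMATION(3*LuxR_protein, 3*AHL_molecule, 3*LuxR_AHL_complex)"
        )
        fragment = expand_construct(construct, "p_process_0")
        (transition,) = fragment.transitions
        assert "LuxR_AHL_complex" in transition.name
        inputs = {(a.place, a.weight) for a in transition.arcs if a.kind == ARC_INPUT}
        outputs = {(a.place, a.weight) for a in transition.arcs if a.kind == ARC_OUTPUT}
        assert inputs == {("LuxR_protein", 3), ("AHL_molecule", 3)}
        assert outputs == {("LuxR_AHL_complex", 3)}

    def test_degradation_is_a_sink(self):
        construct = _parse_construct("DEGRADATION(X_protein)")
        (transition,) = expand_construct(construct, "p_process_0").transitions
        kinds = [a.kind for a in transition.arcs]
        assert kinds == [ARC_INPUT]
        assert transition.arcs[0].weight == 1

    def test_transcription_with_inhibitor_role(self):
        construct = _parse_construct(
            "TRANSCRIPTION(LuxI_gene, LuxI_mRNA, INHIBITORS(LacI_protein))"
        )
        (transition,) = expand_construct(construct, "p_process_0").transitions
        by_kind = {a.kind: a for a in transition.arcs}
        assert by_kind[ARC_READ].place == "LuxI_gene"  # gene is never consumed
        assert by_kind[ARC_OUTPUT].place == "LuxI_mRNA"
        assert by_kind[ARC_INHIBITOR].place == "LacI_protein"
        assert by_kind[ARC_INHIBITOR].weight == 1

    def test_enzyme_on_read_arc(self):
        construct = _parse_construct(
            "ENZYMATIC_REACTION(LuxI_protein, SAM_molecule + ACP_molecule -> AHL_molecule)"
        )
        (transition,) = expand_construct(construct, "x").transitions
        read = [a.place for a in transition.arcs if a.kind == ARC_READ]
        consumed = sorted(a.place for a in transition.arcs if a.kind == ARC_INPUT)
        assert read == ["LuxI_protein"]
        assert consumed == ["ACP_molecule", "SAM_molecule"]

    def test_names_embed_kind_or_product(self):
        for line, token in [
            ("DEGRADATION(X_protein)", "degradation_X_protein"),
            ("TRANSLATION(X_mRNA, X_protein)", "translation_X_protein"),
            ("CUSTOM_PROCESS( -> Z_molecule)", "custom_Z_molecule"),
        ]:
            (transition,) = expand_construct(_parse_construct(line), "pfx").transitions
            assert token in transition.name


class TestCompileWater:
    def test_structure(self, water_fixture):
        model = compile_module(parse(water_fixture.source))
        assert list(model.top_net.places) == ["s"]
        assert model.top_net.places["s"].net_token is model.scope_nets["s"]
        net = model.scope_nets["s"]
        assert set(net.places) == {"H2_molecule", "O2_molecule", "H2O_molecule"}
        (transition,) = net.transitions.values()
        weights = {a.place: a.weight for a in transition.arcs}
        assert weights == {"H2_molecule": 2, "O2_molecule": 1, "H2O_molecule": 2}

    def test_initial_marking_applied(self, water_model):
        net = water_model.scope_nets["s"]
        assert net.places["H2_molecule"].count() == 4
        assert net.places["O2_molecule"].count() == 2


class TestCompileConsortium:
    def test_top_net_diffusion_wiring(self, consortium_model):
        top = consortium_model.top_net
        assert set(top.places) == {"producer", "sensor"}
        diffusion = [t for t in top.transitions.values() if t.name.startswith("diff_")]
        assert {t.name for t in diffusion} == {
            "diff_AHL_molecule_producer_to_sensor",
            "diff_AHL_molecule_sensor_to_producer",
        }

    def test_mirror_bindings_for_diffusible_entity(self, consortium_model):
        pairs = {(b.upper[1], b.lower) for b in consortium_model.bindings}
        assert ("producer", ("producer", "AHL_molecule")) in pairs
        assert ("sensor", ("sensor", "AHL_molecule")) in pairs

    def test_effective_process_timescales(self, consortium_model):
        producer = consortium_model.scope_nets["producer"]
        ahl = [t for t in producer.transitions.values() if t.name.startswith("AHL_production")]
        assert ahl and all(t.timescale == 2 for t in ahl)
        turnover = [t for t in producer.transitions.values() if t.name.startswith("LacI_turnover")]
        assert turnover and all(t.timescale == 1 for t in turnover)
        sensor = consortium_model.scope_nets["sensor"]
        gfp = [t for t in sensor.transitions.values() if t.name.startswith("GFP_production")]
        assert gfp and all(t.timescale == 3 for t in gfp)

    def test_place_stitching_no_duplicates(self, consortium_model):
        producer = consortium_model.scope_nets["producer"]
        # one place per distinct entity: shared LacI/LuxI names stitch together
        assert sorted(producer.places) == sorted(set(producer.places))
        assert "LacI_protein" in producer.places

    def test_no_diffusion_no_top_transitions(self):
        src = (
            "MODULE m\n    TIMESCALE 1\n    SCOPE a(0, 0)\n"
            "        PROCESS p\n            TIMESCALE 1\n"
            "            DEGRADATION(x_protein)\n"
        )
        model = compile_module(parse(src))
        assert model.top_net.transitions == {}

    def test_compilation_is_deterministic(self, consortium_fixture):
        first = compile_module(parse(consortium_fixture.source))
        second = compile_module(parse(consortium_fixture.source))
        assert structure_signature(first) == structure_signature(second)
        assert model_manifest(first) == model_manifest(second)

    def test_invalid_module_rejected(self):
        src = "MODULE m\n    TIMESCALE 1\n    SCOPE a(0, 0)\n    SCOPE b(0, 0)\n"
        with pytest.raises(CompileError, match="duplicate coordinate"):
            compile_module(parse(src))


class TestInstanceNames:
    def test_rgb_progressive_numbering(self, rgb_fixture):
        module = parse(rgb_fixture.source)
        registry = assign_instance_names(module)
        cd19 = sorted(v for v in registry.values() if v.startswith("CD19_production"))
        assert cd19[0] == "CD19_production_process_0"
        assert cd19[1] == "CD19_production_process_1"
        assert len(cd19) == 24  # every sender cell instantiates it once

    def test_single_use_gets_suffix_zero(self, water_fixture):
        registry = assign_instance_names(parse(water_fixture.source))
        assert registry == {"s:0": "reaction_process_0"}

    def test_three_uses_numbered_in_source_order(self):
        src = (
            "MODULE m\n    TIMESCALE 1\n"
            "    SCOPE a(0, 0)\n        PROCESS p\n            TIMESCALE 1\n"
            "            DEGRADATION(x_protein)\n"
            "    SCOPE b(1, 0)\n        PROCESS p\n"
            "    SCOPE c(2, 0)\n        PROCESS p\n"
        )
        registry = assign_instance_names(parse(src))
        assert [registry[k] for k in ["a:0", "b:0", "c:0"]] == [
            "p_process_0", "p_process_1", "p_process_2",
        ]


class TestWiring:
    def test_unidirectional_diffusion_single_transition(self):
        src = (
            "MODULE m\n    TIMESCALE 1\n    SCOPE a(0, 0)\n    SCOPE b(1, 0)\n"
            "    DIFFUSION(x_molecule, a -> b)\n"
        )
        model = compile_module(parse(src))
        assert list(model.top_net.transitions) == ["diff_x_molecule_a_to_b"]

    def test_grid_wide_diffusion_counts_adjacent_pairs(self):
        # 2x2 grid: 6 Moore-adjacent pairs -> 12 directed transitions
        src = (
            "MODULE m\n    TIMESCALE 1\n"
            "    SCOPE a(0, 0)\n    SCOPE b(1, 0)\n    SCOPE c(0, 1)\n    SCOPE d(1, 1)\n"
            "    DIFFUSION(x_molecule, all)\n"
        )
        model = compile_module(parse(src))
        assert len(model.top_net.transitions) == 12

    def test_plasmid_chain_two_channels(self, plasmid_fixture):
        model = compile_module(parse(plasmid_fixture.source))
        assert set(model.channels) == {
            "jux_ssRplasmid_molecule_donor_to_pilus",
            "jux_ssRplasmid_molecule_pilus_to_transconjugant",
        }

    def test_rgb_center_engages_all_eight_neighbors(self, rgb_fixture):
        model = compile_module(parse(rgb_fixture.source))
        outbound = [c for c in model.channels if c.startswith("jux_GFPlig_protein_cellB")]
        inbound = [c for c in model.channels if c.endswith("_to_cellB_2_2")]
        assert len(outbound) == 8
        assert len(inbound) == 8

    def test_emit_without_receiver_omitted_with_warning(self, caplog):
        src = (
            "MODULE m\n    TIMESCALE 1\n"
            "    SCOPE a(0, 0)\n        JUXTACRINE_SIGNAL(emit, x_molecule, b)\n"
            "    SCOPE b(1, 0)\n"
        )
        with caplog.at_level(logging.WARNING):
            model = compile_module(parse(src))
        assert model.channels == {}
        assert any("no matching receive" in r.message for r in caplog.records)
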