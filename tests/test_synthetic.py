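"""Generator behavior: contexts, seeding, noise model, planted effects."""

import numpy as np
import pytest

from methbin import (
    Compartment,
    DmrRequest,
    ReferenceModel,
    SampleProfile,
    build_reference,
    plant_dmrs,
    simulate_sample,
)
from methbin.synthetic import cytosine_contexts

CTX = ("CG", "CHG", "CHH")


class TestContexts:
    def test_hand_enumerated_ten_mer(self):
        # A C G T T C C A G G  — worked out by hand, both strands
        pos, strand, ctx = cytosine_contexts("ACGTTCCAGG")
        got = {(int(p), "+-"[s]): CTX[c] for p, s, c in zip(pos, strand, ctx)}
        assert got == {
            (1, "+"): "CG",   # C G...
            (5, "+"): "CHH",  # C C A
            (6, "+"): "CHG",  # C A G
            (2, "-"): "CG",   # G preceded by C
            (8, "-"): "CHG",  # ..C A G
            (9, "-"): "CHH",  # ..A G G
        }

    def test_acgt_plus_strand_cg(self):
        pos, strand, ctx = cytosine_contexts("ACGT")
        plus = [(p, CTX[c]) for p, s, c in zip(pos, strand, ctx) if s == 0]
        assert (1, "CG") in plus

    def test_every_cytosine_assigned_exactly_once(self, small_ref):
        seq = small_ref.sequences["chr1"]
        pos, strand, ctx = cytosine_contexts(seq)
        n_c = seq.count("C") + seq.count("G")
        assert len(pos) == n_c
        assert set(np.unique(ctx)) <= {0, 1, 2}


class TestBuildReference:
    def test_seeded_determinism(self):
        a = build_reference({"chr1": 100_000}, seed=7)
        b = build_reference({"chr1": 100_000}, seed=7)
        assert a.sequences == b.sequences
        assert a.compartments == b.compartments

    def test_different_seed_differs(self):
        a = build_reference({"chr1": 100_000}, seed=7)
        b = build_reference({"chr1": 100_000}, seed=8)
        assert a.sequences != b.sequences

    def test_rejects_short_chromosome(self):
        with pytest.raises(ValueError, match="10000"):
            build_reference({"chr1": 500}, seed=1)

    def test_rejects_overfull_fractions(self):
        with pytest.raises(ValueError, match="sum"):
            build_reference({"chr1": 20_000}, seed=1,
                            compartment_fractions={"TE_like": 0.7, "gene_body_CG": 0.5})

    def test_rejects_overlapping_compartments(self):
        ref = build_reference({"chr1": 20_000}, seed=1)
        with pytest.raises(ValueError, match="overlap"):
            ReferenceModel(
                ref.chrom_names, ref.chrom_lengths, ref.sequences,
                [Compartment("chr1", 0, 2000, "TE_like"),
                 Compartment("chr1", 1500, 3000, "unmethylated")],
            )

    def test_context_counts_cover_classes(self, small_ref):
        counts = small_ref.context_counts()
        assert set(counts["class"]) == {"TE_like", "gene_body_CG", "unmethylated"}
        assert counts["n_cytosines"].sum() > 0


class TestSimulateSample:
    def test_seeded_determinism_byte_identical(self, small_ref):
        prof = SampleProfile("s", "control", seed=99)
        a = simulate_sample(small_ref, prof)
        b = simulate_sample(small_ref, prof)
        assert a.calls.equals(b.calls)

    def test_count_conservation(self, simulated_samples):
        for s in simulated_samples.values():
            assert (s.calls["m"] >= 0).all()
            assert (s.calls["m"] <= s.calls["n"]).all()

    def test_no_signal_perfect_conversion_gives_zero(self, small_ref):
        prof = SampleProfile(
            "null", "control", conversion_rate=1.0, mean_coverage=10,
            baseline_methylation={c: (0, 0, 0) for c in
                                  ("TE_like", "gene_body_CG", "unmethylated")},
            seed=3,
        )
        s = simulate_sample(small_ref, prof)
        assert (s.calls["m"] == 0).all()

    def test_conversion_calibration_three_se(self, small_ref):
        c = 0.97
        prof = SampleProfile(
            "nc", "control", conversion_rate=c, mean_coverage=30,
            baseline_methylation={cls: (0, 0, 0) for cls in
                                  ("TE_like", "gene_body_CG", "unmethylated")},
            seed=4,
        )
        s = simulate_sample(small_ref, prof)
        m, n = s.calls["m"].sum(), s.calls["n"].sum()
        se = np.sqrt((1 - c) * c / n)
        assert abs(m / n - (1 - c)) < 3 * se

    def test_compartment_fidelity(self, small_ref, simulated_samples):
        s = next(iter(simulated_samples.values()))
        calls = s.calls[s.calls["context"] == "CG"]
        pos = calls["pos"].to_numpy()
        cls = small_ref.compartment_classes_at("chr1", pos)
        te = calls[cls == 0]
        un = calls[cls == 2]
        assert te["m"].sum() / te["n"].sum() > un["m"].sum() / un["n"].sum() + 0.2


class TestPlantDmrs:
    def test_shared_request_bookkeeping(self, small_ref, roster_profiles):
        truth = plant_dmrs([DmrRequest(10, "CG", "hyper", 0.5)],
                           small_ref, roster_profiles, seed=5)
        assert len(truth.planted_dmrs) == 10
        ivs = truth.shared_dmr_intervals()
        assert all(len(iv) >= 100 for iv in ivs)
        for a, b in zip(ivs, ivs[1:]):
            assert b.start >= a.end or b.chrom != a.chrom
        # shared records name every mutant
        assert all(set(d.affected_sample_ids) == {"mutA", "mutB"}
                   for d in truth.planted_dmrs)

    def test_private_request_recorded_as_hypervariable(self, small_truth):
        assert len(small_truth.planted_dmrs) == 6
        assert len(small_truth.hypervariable_regions) == 2
        assert all(set(h.deltas) == {"mutA"}
                   for h in small_truth.hypervariable_regions)

    def test_delta_exceeding_probability_bounds_rejected(self, small_ref, roster_profiles):
        with pytest.raises(ValueError, match=r"outside \[0, 1\]"):
            plant_dmrs([DmrRequest(1, "CG", "hyper", 0.5, compartment_class="TE_like")],
                       small_ref, roster_profiles, seed=5)

    def test_overfull_request_reports_shortfall(self, small_ref, roster_profiles):
        with pytest.raises(ValueError, match="cannot place"):
            plant_dmrs([DmrRequest(100_000, "CG", "hyper", 0.5)],
                       small_ref, roster_profiles, seed=5)

    def test_planted_effect_visible_in_simulation(self, small_ref, small_truth,
                                                  simulated_samples):
        d = small_truth.planted_dmrs[0]
        mut = simulated_samples["mutA"].calls
        ctl = simulated_samples["ctlA"].calls
        sel = lambda df: df[(df["pos"] >= d.start) & (df["pos"] < d.end)
                            & (df["context"] == "CG")]
        lm = sel(mut)["m"].sum() / sel(mut)["n"].sum()
        lc = sel(ctl)["m"].sum() / sel(ctl)["n"].sum()
        assert lm - lc > 0.3
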