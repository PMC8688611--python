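"""Plate forward model: placement, development transport, reads, grid math."""
import math

import numpy as np
import pytest

from actlc.decay_chain import Inventory, activities, evolve
from actlc.tlc_plate_model import (
    DOTA_PROFILE,
    MACROPA_PROFILE,
    ChelatorProfile,
    DetectionModel,
    DevelopmentModel,
    equilibrium_daughters,
    quantify_grid,
    read_grid_counts,
    read_rcp,
    sample_at_equilibrium,
    section_signals,
    spot_and_develop,
)


def make_plate(chain, dev, p, profile):
    return spot_and_develop(sample_at_equilibrium(p, profile, chain), dev, chain)


class TestQuantifyGrid:
    @pytest.mark.parametrize(
        "counts,product,expected",
        [
            ([1000, 0, 0], [0], 1.0),
            ([800, 100, 100], [0], 0.8),
            ([0, 50, 950], [0], 0.0),
            ([400, 400, 100, 100], [0, 1], 0.8),
        ],
    )
    def test_ratio_of_product_counts(self, counts, product, expected):
        assert quantify_grid(counts, product) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            quantify_grid([0, 0, 0], [0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            quantify_grid([10, -1, 0], [0])

    def test_grid_count_file_roundtrip(self, tmp_path):
        path = tmp_path / "grid.csv"
        path.write_text(
            "plate_id,box_index,rf_low,rf_high,counts,is_product\n"
            "A,0,0.0,0.3,900,1\nA,1,0.3,0.7,50,0\nA,2,0.7,1.0,50,0\n"
            "B,0,0.0,0.3,10,1\nB,1,0.3,0.7,0,0\nB,2,0.7,1.0,90,0\n"
        )
        out = read_grid_counts(path)
        assert dict(zip(out.plate_id, out.rcp)) == pytest.approx(
            {"A": 0.9, "B": 0.1}
        )

    def test_grid_count_file_missing_column(self, tmp_path):
        path = tmp_path / "grid.csv"
        path.write_text("plate_id,counts\nA,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_grid_counts(path)


class TestSpotAndDevelop:
    def test_fully_bound_no_daughters_no_migration_all_in_s1(self, chain):
        sample = sample_at_equilibrium(1.0, MACROPA_PROFILE, chain)
        sample = type(sample)(
            bound_fraction=1.0,
            chelator=MACROPA_PROFILE,
            daughter_state_at_spotting=Inventory({}),
        )
        dev = DevelopmentModel(migration_to_mid=0.0, migration_to_front=0.0)
        plate = spot_and_develop(sample, dev, chain)
        assert plate.sections[1].total_atoms() == 0.0
        assert plate.sections[2].total_atoms() == 0.0
        assert plate.sections[0].total_atoms() == pytest.approx(1.0, rel=1e-12)

    def test_unbound_macropa_sample_all_in_s3(self, chain, dev):
        plate = make_plate(chain, dev, 0.0, MACROPA_PROFILE)
        assert plate.sections[0].total_atoms() == 0.0
        assert plate.sections[1].total_atoms() == 0.0

    def test_dota_chelation_places_spotted_bi_and_pb_at_origin(self, chain, dev):
        plate = make_plate(chain, dev, 0.5, DOTA_PROFILE)
        spotted = equilibrium_daughters(chain)
        # Bi-213 decays during the run; S1 holds at least the surviving
        # chelated share plus half the in-run ingrowth that stayed put
        lam_bi = chain.nuclides["Bi-213"].decay_constant
        survived = spotted.atoms["Bi-213"] * math.exp(
            -lam_bi * dev.duration_min / 60.0
        )
        assert plate.sections[0].atoms["Bi-213"] >= survived
        # macropa spot of the same purity holds no chelated Bi at the origin
        plate_m = make_plate(chain, dev, 0.5, MACROPA_PROFILE)
        assert plate_m.sections[0].atoms["Bi-213"] < plate.sections[0].atoms["Bi-213"]

    def test_event_ledger_oracle(self, chain, dev):
        """The expm transport solution must agree with a step-by-step decay
        ledger that routes each birth by the section it occurs in."""
        profile = DOTA_PROFILE
        p = 0.5
        s1 = {chain.root: p}
        s3 = {chain.root: 1.0 - p}
        for name, n in equilibrium_daughters(chain).atoms.items():
            bound = profile.solution_chelation.get(name.split("-")[0], 0.0)
            if bound:
                s1[name] = s1.get(name, 0.0) + bound * n
            if bound < 1.0:
                s3[name] = s3.get(name, 0.0) + (1.0 - bound) * n

        steps = 6000
        tau = dev.duration_min / 60.0
        dt = tau / steps
        m2, m3 = dev.migration_to_mid, dev.migration_to_front
        route = [(1.0 - m2 - m3, m2, m3), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)]
        secs = [dict(s1), {}, dict(s3)]
        for _ in range(steps):
            nxt = [dict(s) for s in secs]
            for si, sec in enumerate(secs):
                for n, atoms in sec.items():
                    li = chain.nuclides[n].decay_constant
                    if li == 0.0 or atoms == 0.0:
                        continue
                    dec = atoms * (1.0 - math.exp(-li * dt))
                    nxt[si][n] -= dec
                    for d, b in chain.effective_daughters(n):
                        for st in range(3):
                            if route[si][st]:
                                nxt[st][d] = nxt[st].get(d, 0.0) + dec * b * route[si][st]
            secs = nxt

        plate = spot_and_develop(
            sample_at_equilibrium(p, profile, chain), dev, chain
        )
        # the Euler ledger is first-order accurate; tolerance reflects dt
        for si in range(3):
            for n, ref in secs[si].items():
                if ref > 1e-12:
                    got = plate.sections[si].atoms.get(n, 0.0)
                    assert got == pytest.approx(ref, rel=2e-3)

    def test_unknown_sample_daughter_rejected(self, chain, dev):
        from actlc.tlc_plate_model import SampleComposition

        bad = SampleComposition(0.5, MACROPA_PROFILE, Inventory({"Ra-226": 1.0}))
        with pytest.raises(KeyError):
            spot_and_develop(bad, dev, chain)


class TestReadRcp:
    def test_pure_origin_plate_reads_one(self, chain, det):
        dev = DevelopmentModel(migration_to_mid=0.0, migration_to_front=0.0)
        from actlc.tlc_plate_model import SampleComposition

        sample = SampleComposition(1.0, MACROPA_PROFILE, Inventory({}))
        plate = spot_and_develop(sample, dev, chain)
        for t in (0.0, 0.5, 26.0):
            assert read_rcp(plate, t, det, chain) == pytest.approx(1.0)

    def test_zero_signal_plate_rejected(self, chain, det, dev):
        from actlc.tlc_plate_model import PlateState

        empty = PlateState(
            sections=(Inventory({}), Inventory({}), Inventory({"Bi-209": 1.0}))
        )
        with pytest.raises(ValueError, match="zero total signal"):
            read_rcp(empty, 1.0, det, chain)

    def test_high_purity_underestimated_early(self, chain, det, dev):
        plate = make_plate(chain, dev, 0.95, MACROPA_PROFILE)
        assert read_rcp(plate, 0.5, det, chain) < read_rcp(plate, 26.0, det, chain)

    def test_low_purity_dota_overestimated_early(self, chain, det, dev):
        plate = make_plate(chain, dev, 0.25, DOTA_PROFILE)
        assert read_rcp(plate, 0.5, det, chain) > read_rcp(plate, 26.0, det, chain)

    @pytest.mark.parametrize("profile", [MACROPA_PROFILE, DOTA_PROFILE])
    def test_equilibrium_read_recovers_bound_fraction(self, chain, det, dev, profile):
        for p in np.linspace(0.0, 1.0, 9):
            plate = make_plate(chain, dev, float(p), profile)
            assert abs(read_rcp(plate, 26.0, det, chain) - p) <= 0.01

    @pytest.mark.parametrize("profile", [MACROPA_PROFILE, DOTA_PROFILE])
    def test_late_reads_converge_to_equilibrium_value(self, chain, det, dev, profile):
        """By ~18 h the spotted Pb-209 excess has decayed below 0.5 pp."""
        for p in (0.0, 0.3, 0.7, 0.98):
            plate = make_plate(chain, dev, p, profile)
            ref = read_rcp(plate, 26.0, det, chain)
            for t in (18.0, 20.0, 24.0):
                assert abs(read_rcp(plate, t, det, chain) - ref) <= 0.005

    def test_mid_cluster_dota_bias_shrinks_and_clears_5pp_by_3_5h(
        self, chain, det, dev
    ):
        """Mid-purity DOTA bias scales with the unbound fraction (1 - p) and
        decays with the spotted Bi-213/Pb-209 excess; it drops below 5 pp by
        the 3.5 h read for the whole 0.50-0.75 cluster."""
        for p in (0.5, 0.625, 0.75):
            plate = make_plate(chain, dev, p, DOTA_PROFILE)
            ref = read_rcp(plate, 26.0, det, chain)
            biases = [
                abs(read_rcp(plate, t, det, chain) - ref)
                for t in (0.5, 2.0, 3.5, 5.0, 6.5)
            ]
            assert all(b <= a for a, b in zip(biases, biases[1:]))
            assert biases[2] <= 0.05

    def test_signal_conserved_under_uniform_efficiency(self, chain, dev):
        """With equal efficiencies the plate total equals an unspotted
        aliquot of the same age: transport only relocates atoms."""
        det_u = DetectionModel.uniform()
        plate = make_plate(chain, dev, 0.7, MACROPA_PROFILE)
        start = {chain.root: 1.0}
        start.update(equilibrium_daughters(chain).atoms)
        for t in (0.5, 6.5, 26.0):
            total = sum(section_signals(plate, t, det_u, chain))
            aliquot = evolve(
                chain, Inventory(start), dev.duration_min / 60.0 + t
            )
            ref = sum(activities(chain, aliquot).values())
            assert total == pytest.approx(ref, rel=1e-9)


class TestValidation:
    def test_migration_fractions_must_fit_in_unit_interval(self):
        with pytest.raises(ValueError):
            DevelopmentModel(migration_to_mid=0.6, migration_to_front=0.5)

    def test_detection_needs_a_nonzero_weight(self):
        with pytest.raises(ValueError):
            DetectionModel({"alpha": 0.0, "beta": 0.0})

    def test_chelation_fraction_bounds(self):
        with pytest.raises(ValueError):
            ChelatorProfile("bad", {"Bi": 1.5})
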