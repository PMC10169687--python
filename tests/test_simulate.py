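"""Synthetic recording and cohort generator."""

import numpy as np
import pytest

import eegspatcorr as esc
from eegspatcorr.envelope import decimate_envelope
from eegspatcorr.pipeline import mpsi_table_for_recording

from conftest import two_channel_config


THETA = {"theta": (3.0, 7.0)}


def mpsi_pair(recording, ch_a, ch_b, condition="eyes_closed"):
    table = mpsi_table_for_recording(
        recording,
        [(ch_a, ch_b)],
        THETA,
        ("infraslow",),
        (condition,),
        participant="x",
    )
    return float(table["m_psi"].iloc[0])


def single_condition_config(**kwargs):
    defaults = dict(
        channel_labels=("FC1", "FT7"),
        duration=600.0,
        carrier_bands=(("theta", 3.0, 7.0),),
        condition_schedule=[("eyes_closed", 600.0)],
        seed=0,
    )
    defaults.update(kwargs)
    return esc.SimulationConfig(**defaults)


class TestSimulationConfig:
    def test_schedule_must_tile_duration(self):
        with pytest.raises(ValueError, match="tile"):
            two_channel_config(condition_schedule=[("eyes_closed", 100.0)])

    def test_too_few_envelope_cycles_rejected(self):
        with pytest.raises(ValueError, match="cycles"):
            two_channel_config(
                duration=20.0, condition_schedule=[("eyes_closed", 20.0)]
            )

    def test_modulation_depth_bounds(self):
        with pytest.raises(ValueError, match="modulation_depth"):
            two_channel_config(modulation_depth=1.0)

    def test_intervals_property(self):
        cfg = two_channel_config()
        ivs = cfg.intervals
        assert len(ivs) == 10
        assert ivs[0].condition == "eyes_closed"
        assert ivs[1].condition == "eyes_open"
        assert ivs[-1].end == pytest.approx(300.0)
        assert cfg.conditions == ["eyes_closed", "eyes_open"]

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            esc.CouplingSpec(base_kappa=-1.0)


class TestGenerateRecording:
    def test_deterministic(self):
        cfg = two_channel_config(seed=5)
        r1 = esc.generate_recording(cfg)
        r2 = esc.generate_recording(cfg)
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_seeds_differ(self):
        cfg = two_channel_config()
        r1 = esc.generate_recording(cfg, seed=1)
        r2 = esc.generate_recording(cfg, seed=2)
        assert not np.array_equal(r1.data, r2.data)

    def test_shape_and_intervals(self):
        cfg = two_channel_config()
        rec = esc.generate_recording(cfg)
        assert rec.data.shape == (2, 150000)
        assert rec.fs == 500.0
        assert [iv.condition for iv in rec.condition_intervals[:2]] == [
            "eyes_closed",
            "eyes_open",
        ]

    def test_missing_seed_rejected(self):
        cfg = two_channel_config(seed=None)
        with pytest.raises(ValueError, match="seed"):
            esc.generate_recording(cfg)

    def test_unknown_override_region_rejected(self):
        cfg = two_channel_config(
            coupling=esc.CouplingSpec(
                overrides={("nowhere", "left_frontal", "theta", "eyes_closed"): 1.0}
            )
        )
        with pytest.raises(KeyError, match="nowhere"):
            esc.generate_recording(cfg)

    def test_carrier_spectrum_peaks_in_theta(self):
        cfg = two_channel_config()
        rec = esc.generate_recording(cfg)
        freqs, mag = esc.spectrum(rec.data[0], rec.fs)
        assert esc.band_peak_check(freqs, mag, "theta")

    def test_envelope_fluctuation_is_infraslow(self):
        cfg = single_condition_config()
        rec = esc.generate_recording(cfg)
        _, coeffs = esc.design_bandpass(3.0, 7.0, rec.fs)
        theta = esc.filtfilt_zero_phase(rec.data[0], coeffs)
        env = esc.analytic_envelope(theta, rec.fs)
        dec = decimate_envelope(env, 10.0)
        vals = dec.values[200:-200]
        freqs, mag = esc.spectrum(vals - vals.mean(), 10.0)
        peak = freqs[(freqs > 0.01) & (freqs < 5)][
            np.argmax(mag[(freqs > 0.01) & (freqs < 5)])
        ]
        assert 0.04 <= peak <= 0.12


class TestCouplingControlsMPsi:
    def test_mpsi_monotone_in_kappa(self):
        mpsis = []
        for kappa in [0.0, 1.0, 5.0, 1000.0]:
            cfg = single_condition_config(
                coupling=esc.CouplingSpec(base_kappa=kappa), seed=11
            )
            rec = esc.generate_recording(cfg)
            mpsis.append(mpsi_pair(rec, "FC1", "FT7"))
        assert np.all(np.diff(mpsis) > 0)
        assert mpsis[0] < 0.65  # near-chance when uncoupled
        assert mpsis[-1] > 0.95  # near-ceiling when tightly coupled

    def test_pair_deficit_is_strongest_on_target_pair(self):
        regions = {"rx": ("FC1",), "ry": ("FT7",), "rz": ("CZ",)}
        base = dict(
            channel_labels=("FC1", "FT7", "CZ"),
            duration=600.0,
            carrier_bands=(("theta", 3.0, 7.0),),
            condition_schedule=[("eyes_closed", 300.0), ("eyes_open", 300.0)],
            regions=regions,
            seed=3,
        )
        plain = esc.generate_recording(esc.SimulationConfig(**base))
        deficit = esc.generate_recording(
            esc.SimulationConfig(
                **base,
                coupling=esc.CouplingSpec(
                    base_kappa=10.0,
                    overrides={("rx", "ry", "theta", "eyes_closed"): 0.5},
                ),
            )
        )
        target = mpsi_pair(deficit, "FC1", "FT7")
        collateral = mpsi_pair(deficit, "FC1", "CZ")
        baseline = mpsi_pair(plain, "FC1", "FT7")
        assert target < collateral < baseline
        # the deficit is condition-specific: eyes-open coupling stays intact
        assert mpsi_pair(deficit, "FC1", "FT7", "eyes_open") > target + 0.1


class TestCohort:
    def _cohort_config(self, **kwargs):
        base = esc.SimulationConfig(
            channel_labels=("FC1", "FT7"),
            duration=100.0,
            carrier_bands=(("theta", 3.0, 7.0),),
            condition_schedule=esc.alternating_schedule(10, 10.0),
        )
        defaults = dict(
            n_per_group={"Control": 4, "cMDD": 3, "pMDD": 3, "None": 0},
            base=base,
            seed=99,
        )
        defaults.update(kwargs)
        return esc.CohortConfig(**defaults)

    def test_bookkeeping(self):
        cohort = esc.generate_cohort(self._cohort_config())
        assert len(cohort) == 10
        records = [r for r, _ in cohort]
        assert [r.id for r in records] == [f"sub-{i:03d}" for i in range(1, 11)]
        groups = esc.participants_group_map(records)
        assert sorted(groups.values()).count("Control") == 4
        assert sorted(groups.values()).count("cMDD") == 3
        assert sorted(groups.values()).count("pMDD") == 3

    def test_bdi_respects_group_ranges(self):
        cohort = esc.generate_cohort(self._cohort_config())
        groups = esc.participants_group_map([r for r, _ in cohort])
        for record, _ in cohort:
            if groups[record.id] == "Control":
                assert record.bdi <= 7
            else:
                assert record.bdi >= 13

    def test_classification_matches_group(self):
        cohort = esc.generate_cohort(self._cohort_config())
        for record, _ in cohort:
            assert esc.classify_participant(record.bdi, record.clinical) == record.group

    def test_deterministic(self):
        c1 = esc.generate_cohort(self._cohort_config())
        c2 = esc.generate_cohort(self._cohort_config())
        for (r1, rec1), (r2, rec2) in zip(c1, c2):
            assert r1 == r2
            np.testing.assert_array_equal(rec1.data, rec2.data)

    def test_effect_for_empty_group_warns(self):
        with pytest.warns(UserWarning, match="empty group"):
            self._cohort_config(
                n_per_group={"Control": 2, "cMDD": 0, "pMDD": 0, "None": 0}
            )

    def test_invalid_bdi_ranges_rejected(self):
        with pytest.raises(ValueError, match="Control"):
            self._cohort_config(
                bdi_ranges={
                    "Control": (0, 10),
                    "cMDD": (13, 36),
                    "pMDD": (13, 36),
                    "None": (13, 36),
                }
            )

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            self._cohort_config(n_per_group={"Martians": 3})
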