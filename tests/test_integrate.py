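import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clipsplice.integrate import (
    build_rna_map,
    clip_enrichment_in_changed_introns,
    coregulation_overlap,
    dpir_by_clip_status,
    rna_map_table,
)
from clipsplice.peaks import Peak


def mk_peak(summit, chrom="chr1", strand="+"):
    return Peak(chrom, strand, summit - 5, summit + 5, summit, 10, 0.001)


def dpir_frame(plus, minus):
    rows = [dict(intron_id=f"p{i}", dpir=v, clip_status="CLIP_plus") for i, v in enumerate(plus)]
    rows += [dict(intron_id=f"m{i}", dpir=v, clip_status="CLIP_minus") for i, v in enumerate(minus)]
    return pd.DataFrame(rows)


class TestDpirByClipStatus:
    def test_identical_groups_p_half(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 3, 200)
        out = dpir_by_clip_status(dpir_frame(vals, vals))
        assert 0.4 < out["p_value"] < 0.6

    def test_exact_one_sided_enumeration(self):
        out = dpir_by_clip_status(dpir_frame([6, 7, 8], [0, 0, 1]))
        assert out["p_value"] == pytest.approx(0.05)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        plus = rng.normal(3, 2, 50)
        minus = rng.normal(0, 2, 50)
        p1 = dpir_by_clip_status(dpir_frame(plus, minus))["p_value"]
        p2 = dpir_by_clip_status(dpir_frame(plus + 7, minus + 7))["p_value"]
        assert p1 == pytest.approx(p2)

    def test_changed_fractions(self):
        out = dpir_by_clip_status(dpir_frame([10, 10, -10, 0], [0, 0, 0, 0]))
        g = out["groups"]
        assert g["CLIP_plus"]["frac_up"] == pytest.approx(0.5)
        assert g["CLIP_plus"]["frac_down"] == pytest.approx(0.25)
        assert g["CLIP_minus"]["frac_up"] == 0.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            dpir_by_clip_status(dpir_frame([1.0], []))

    def test_coupled_simulation_recovered(self):
        rng = np.random.default_rng(2)
        noise = lambda n: rng.normal(0, 3, n)
        plus = noise(300) + np.where(rng.random(300) < 0.5, 10.0, 0.0)
        minus = noise(300)
        out = dpir_by_clip_status(dpir_frame(plus, minus))
        assert out["p_value"] < 1e-3
        assert out["groups"]["CLIP_plus"]["frac_up"] > out["groups"]["CLIP_minus"]["frac_up"]


class TestClipEnrichment:
    def test_matches_hypergeometric(self):
        universe = [f"i{j}" for j in range(40)]
        clip_plus = universe[:20]
        changed = universe[:10]  # all CLIP+
        out = clip_enrichment_in_changed_introns(changed, clip_plus, universe)
        expect = stats.hypergeom.sf(10 - 1, 40, 20, 10)
        assert out["p_value"] == pytest.approx(expect)
        assert out["n_changed_clip_plus"] == 10

    def test_exact_extreme_table(self):
        universe = [f"i{j}" for j in range(20)]
        out = clip_enrichment_in_changed_introns(universe[:10], universe[:10], universe)
        assert out["table"] == [[10, 0], [0, 10]]
        assert out["p_value"] == pytest.approx(1 / 184756)

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        universe = [f"i{j}" for j in range(200)]
        clip_plus = universe[:100]
        pvals = []
        for _ in range(200):
            changed = list(rng.choice(universe, 30, replace=False))
            pvals.append(
                clip_enrichment_in_changed_introns(changed, clip_plus, universe)["p_value"]
            )
        assert np.mean(np.array(pvals) < 0.05) < 0.1


class TestCoregulation:
    def calls(self, deltas, etype="cassette"):
        return pd.DataFrame(
            [
                dict(event_id=f"e{i}", event_type=etype, delta=v)
                for i, v in enumerate(deltas)
            ]
        )

    def test_identical_tables_full_overlap(self):
        a = self.calls([20, -30, 5, 15])
        out = coregulation_overlap(a, a, threshold=10)
        up = out[(out["direction"] == "up")].iloc[0]
        assert up["overlap"] == 2 and up["a_only"] == 0 and up["b_only"] == 0
        down = out[(out["direction"] == "down")].iloc[0]
        assert down["overlap"] == 1

    def test_disjoint_sets_no_overlap(self):
        a = self.calls([20, 0, 0, 0])
        b = self.calls([0, 0, 0, 20])
        out = coregulation_overlap(a, b, threshold=10)
        up = out[out["direction"] == "up"].iloc[0]
        assert up["overlap"] == 0 and up["a_only"] == 1 and up["b_only"] == 1

    def test_universe_restricted_to_shared_events(self):
        a = self.calls([20, 20])
        b = self.calls([20])  # only e0 shared
        out = coregulation_overlap(a, b, threshold=10)
        assert out["n_universe"].iloc[0] == 1

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        da, db = rng.normal(0, 15, 300), rng.normal(0, 15, 300)
        a, b = self.calls(da), self.calls(db)
        out = coregulation_overlap(a, b, threshold=10).set_index("direction")
        in_a = {i for i, v in enumerate(da) if v > 10}
        in_b = {i for i, v in enumerate(db) if v > 10}
        assert out.loc["up", "overlap"] == len(in_a & in_b)
        assert out.loc["up", "a_only"] == len(in_a - in_b)


class TestRnaMap:
    def event_frame(self):
        # + strand cassette: C1 (1000,1100), intron_up (1100,1400),
        # CA (1400,1500), intron_down (1500,1800), C2 (1800,1900)
        return pd.DataFrame(
            [
                dict(
                    event_id="ev1", gene_id="g1", event_type="cassette",
                    chrom="chr1", strand="+",
                    c1_start=1000, c1_end=1100, ex_start=1400, ex_end=1500,
                    c2_start=1800, c2_end=1900,
                    up_intron_id="t1.i1", down_intron_id="t1.i2",
                )
            ]
        )

    def call_frame(self, delta, accepted=True, psi=50.0):
        return pd.DataFrame(
            [dict(event_id="ev1", event_type="cassette", delta=delta,
                  accepted=accepted, psi_control=psi)]
        )

    def test_enhanced_event_upstream_intron_mass(self):
        peaks = [mk_peak(1110)]  # 10 nt into upstream intron (len 300)
        prof = build_rna_map(self.call_frame(-20.0), self.event_frame(), peaks)
        enh = prof["enhanced"]
        assert enh.n_events == 1
        assert enh.intronic["intron_up"][0] == pytest.approx(1.0)  # first of 20 bins
        assert enh.intronic["intron_down"].sum() == 0
        assert sum(v.sum() for v in enh.exonic.values()) == 0
        assert prof["silenced"].n_events == 0 and prof["control"].n_events == 0

    def test_minus_strand_orientation(self):
        ev = self.event_frame()
        ev["strand"] = "-"
        # on -, the transcriptionally upstream intron is the genomic-right one
        peaks = [mk_peak(1790, strand="-")]  # 10 nt into (1500,1800) from its 3'... 5' end
        prof = build_rna_map(self.call_frame(-20.0), ev, peaks)
        assert prof["enhanced"].intronic["intron_up"][0] == pytest.approx(1.0)

    def test_control_group_requires_peak_and_flat_psi(self):
        prof = build_rna_map(
            self.call_frame(2.0, accepted=False, psi=50.0),
            self.event_frame(),
            [mk_peak(1450)],  # inside cassette exon
        )
        ctl = prof["control"]
        assert ctl.n_events == 1
        assert ctl.exonic["CA_5p"].sum() + ctl.exonic["CA_3p"].sum() >= 1

    def test_event_without_peak_in_no_group(self):
        prof = build_rna_map(self.call_frame(-20.0), self.event_frame(), [mk_peak(99999)])
        assert all(prof[g].n_events == 0 for g in prof)

    def test_groups_partition_events(self):
        prof = build_rna_map(self.call_frame(-20.0), self.event_frame(), [mk_peak(1110)])
        assert sum(prof[g].n_events for g in prof) == 1

    def test_exonic_bins(self):
        # summit 7 nt into cassette exon from its 5' end -> bin 1 of CA_5p
        prof = build_rna_map(self.call_frame(-20.0), self.event_frame(), [mk_peak(1407)])
        enh = prof["enhanced"]
        assert enh.exonic["CA_5p"][1] == pytest.approx(1.0)
        # and 92 nt from the 3' end: beyond the 50-nt window
        assert enh.exonic["CA_3p"].sum() == 0

    def test_table_shape(self):
        prof = build_rna_map(self.call_frame(-20.0), self.event_frame(), [mk_peak(1110)])
        tab = rna_map_table(prof)
        assert set(tab["group"]) == {"enhanced", "silenced", "control"}
        n_rows_per_group = 6 * 10 + 2 * 20
        assert len(tab) == 3 * n_rows_per_group

    def test_truthset_recovery_upstream_enrichment(self):
        # planted summits near the upstream-intron 5' ss only for enhanced events
        rng = np.random.default_rng(5)
        rows, calls, peaks = [], [], []
        for i in range(30):
            base = 10_000 * i
            rows.append(
                dict(
                    event_id=f"enh{i}", gene_id=f"g{i}", event_type="cassette",
                    chrom="chr1", strand="+",
                    c1_start=base, c1_end=base + 100,
                    ex_start=base + 400, ex_end=base + 500,
                    c2_start=base + 800, c2_end=base + 900,
                    up_intron_id="", down_intron_id="",
                )
            )
            calls.append(dict(event_id=f"enh{i}", event_type="cassette",
                              delta=-20.0, accepted=True, psi_control=50.0))
            peaks.append(mk_peak(base + 100 + int(rng.integers(10, 60))))
        for i in range(30):
            base = 10_000 * (100 + i)
            rows.append(
                dict(
                    event_id=f"ctl{i}", gene_id=f"gc{i}", event_type="cassette",
                    chrom="chr1", strand="+",
                    c1_start=base, c1_end=base + 100,
                    ex_start=base + 400, ex_end=base + 500,
                    c2_start=base + 800, c2_end=base + 900,
                    up_intron_id="", down_intron_id="",
                )
            )
            calls.append(dict(event_id=f"ctl{i}", event_type="cassette",
                              delta=0.0, accepted=False, psi_control=50.0))
            peaks.append(mk_peak(base + int(rng.integers(100, 800))))  # uniform anywhere
        prof = build_rna_map(pd.DataFrame(calls), pd.DataFrame(rows), peaks)
        near = slice(0, 5)  # first quarter of the upstream intron
        enh = prof["enhanced"].intronic["intron_up"][near].sum()
        ctl = max(prof["control"].intronic["intron_up"][near].sum(), 1e-9)
        assert prof["enhanced"].n_events == 30
        assert enh / ctl > 2
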