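import numpy as np
import pandas as pd
import pytest

import strainkin as sk
from strainkin import coverage as cov
from strainkin.scenarios import hybrid_trio_population
from strainkin.simulate import depth_profiles


@pytest.fixture(scope="module")
def trio():
    pop = hybrid_trio_population(7)
    depth = depth_profiles(pop, mean_depth=50, depth_noise=0.15, seed=8)
    return pop, depth


def _profile(pop, depth, strain, **kw):
    return cov.normalize_windows(depth[strain], pop.layouts, strain=strain,
                                 **kw)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_uniform_depth_normalizes_to_one():
    layouts = sk.make_layout(2, 100_000)
    pop = sk.simulate_founders(layouts, 1, seed=1)
    depth = depth_profiles(pop, mean_depth=30, depth_noise=0, seed=1)["F01"]
    prof = cov.normalize_windows(depth, layouts)
    focal = prof.frame[prof.frame["kind"] == "chromosome"]
    assert np.allclose(focal["norm"], 1.0)
    assert prof.norm_constant == pytest.approx(30.0)


def test_scale_invariance_of_normalized_profile(trio):
    pop, depth = trio
    base = _profile(pop, depth, "HYB_ONE_CHROM")
    doubled = depth["HYB_ONE_CHROM"].assign(
        depth=depth["HYB_ONE_CHROM"]["depth"] * 2)
    prof2 = cov.normalize_windows(doubled, pop.layouts,
                                  strain="HYB_ONE_CHROM")
    assert np.allclose(prof2.norm_constant, 2 * base.norm_constant)
    pd.testing.assert_series_equal(prof2.frame["norm"], base.frame["norm"])


def test_doubling_mean_depth_doubles_raw_only():
    layouts = sk.make_layout(1, 100_000, n_accessory=1)
    pop = sk.simulate_founders(layouts, 1, seed=2)
    d30 = depth_profiles(pop, mean_depth=30, depth_noise=0, seed=1)["F01"]
    d60 = depth_profiles(pop, mean_depth=60, depth_noise=0, seed=1)["F01"]
    assert np.allclose(d60["depth"], 2 * d30["depth"])
    p30 = cov.normalize_windows(d30, layouts)
    p60 = cov.normalize_windows(d60, layouts)
    pd.testing.assert_series_equal(p30.frame["norm"], p60.frame["norm"])


def test_planted_copy_numbers_recovered_within_quarter_unit():
    """Dosages 1-4 (donor chromosomes at 2,4,6,8 copies on a diploid)
    recovered within 0.25 normalized units at 30x with depth noise."""
    layouts = sk.make_layout(4, 100_000, n_species=2)
    pop = sk.simulate_founders(layouts, 1, seed=3)
    chroms = [c.name for c in layouts[0].chromosomes]
    pop.derive(sk.PedigreeRecord(
        "CN", "interspecific_hybrid", ("F01",),
        donor_chrom_copies={"Spar": dict(zip(chroms, [2, 4, 6, 8]))}), 4)
    depth = depth_profiles(pop, mean_depth=30, depth_noise=0.15,
                           seed=5)["CN"]
    prof = cov.normalize_windows(depth, layouts)
    for chrom, dosage in zip(chroms, [1, 2, 3, 4]):
        sub = prof.frame[prof.frame["contig"] == f"Spar_{chrom}"]
        assert abs(sub["norm"].mean() - dosage) < 0.25


def test_subthreshold_windows_masked(trio):
    pop, depth = trio
    prof = _profile(pop, depth, "F01")
    donor = prof.frame[prof.frame["species"] != "Scer"]
    assert donor["masked"].all()
    assert donor["norm"].isna().all()


def test_no_qualifying_window_errors():
    layouts = sk.make_layout(1, 50_000)
    zero = pd.DataFrame({"chrom": ["Scer_chrI"], "start": [0],
                         "end": [50_000], "depth": [0.0]})
    with pytest.raises(ValueError, match="qualifying"):
        cov.normalize_windows(zero, layouts)


def test_negative_depth_rejected():
    layouts = sk.make_layout(1, 50_000)
    bad = pd.DataFrame({"chrom": ["Scer_chrI"], "start": [0],
                        "end": [50_000], "depth": [-1.0]})
    with pytest.raises(ValueError):
        cov.normalize_windows(bad, layouts)


def test_samtools_depth_format_accepted(tmp_path):
    rows = "\n".join(f"Scer_chrI\t{i + 1}\t20" for i in range(200))
    p = tmp_path / "depth.tsv"
    p.write_text(rows + "\n")
    df = cov.read_depth_track(p)
    assert list(df.columns) == ["chrom", "start", "end", "depth"]
    assert df["start"].iloc[0] == 0 and df["end"].iloc[0] == 1


# ---------------------------------------------------------------------------
# species contributions and hybrid calls
# ---------------------------------------------------------------------------

def test_full_donor_genome_detected(trio):
    pop, depth = trio
    contrib = cov.species_contribution(_profile(pop, depth, "HYB_FULL"))
    spar = contrib.species_frame("Spar")
    assert (spar["covered_fraction"] > 0.99).all()
    call = cov.call_hybrid(contrib, "Scer")
    assert call.classification == "near-complete second genome"
    assert call.donor_species == ["Spar"]


def test_no_donor_reads_zero_fractions(trio):
    pop, depth = trio
    contrib = cov.species_contribution(_profile(pop, depth, "F01"))
    donors = contrib.frame[contrib.frame["species"] != "Scer"]
    assert (donors["covered_fraction"] == 0).all()
    assert cov.call_hybrid(contrib, "Scer").classification == "non-hybrid"


def test_single_donor_chromosome_quarter_dosage(trio):
    """NT50 configuration: one donor chromosome, breadth ~1 at normalized
    dosage ~0.25, every other donor chromosome silent."""
    pop, depth = trio
    contrib = cov.species_contribution(_profile(pop, depth,
                                                "HYB_ONE_CHROM"))
    spar = contrib.species_frame("Spar").set_index("chrom")
    assert spar.loc["chrXIII", "covered_fraction"] > 0.95
    assert 0.20 < spar.loc["chrXIII", "mean_norm_depth"] < 0.30
    others = spar.drop("chrXIII")
    assert (others["covered_fraction"] == 0).all()
    call = cov.call_hybrid(contrib, "Scer")
    assert call.donor_chromosomes("Spar") == {"chrXIII"}
    assert call.classification == "partial"


def test_three_species_strain_minor_donor_flagged(trio):
    pop, depth = trio
    contrib = cov.species_contribution(_profile(pop, depth,
                                                "HYB_THREE_SPECIES"))
    call = cov.call_hybrid(contrib, "Scer")
    assert set(call.donor_species) == {"Spar", "Smik"}
    flags = {d.species: d.minor for d in call.donors}
    assert not flags["Spar"] and flags["Smik"]
    assert call.classification == "near-complete second genome"


def test_hybrid_fraction_boundary_is_strict():
    frame = pd.DataFrame({
        "species": ["Scer", "Spar", "Spar"],
        "chrom": ["chrI", "chrI", "chrII"],
        "n_windows": [10, 10, 10],
        "covered_fraction": [1.0, 0.10, 0.0],
        "mean_norm_depth": [1.0, 0.5, 0.0]})
    contrib = cov.SpeciesContribution("s", frame, 0.125)
    assert cov.call_hybrid(contrib, "Scer").donors == []
    frame.loc[1, "covered_fraction"] = 0.101
    assert cov.call_hybrid(contrib, "Scer").donor_species == ["Spar"]


# ---------------------------------------------------------------------------
# accessory loci and markers
# ---------------------------------------------------------------------------

def test_accessory_presence_and_absence(trio):
    pop, depth = trio
    prof = _profile(pop, depth, "F01")  # founders default: all loci present
    call = cov.call_accessory(prof, "wine_circle")
    assert call.present and call.breadth > 0.99
    pop.records["F02"].accessory_content = {"wine_circle": 0}
    d2 = depth_profiles(pop, seed=9)["F02"]
    prof2 = cov.normalize_windows(d2, pop.layouts, strain="F02")
    gone = cov.call_accessory(prof2, "wine_circle")
    assert not gone.present and gone.breadth == 0.0


def test_half_deleted_locus_present_at_boundary():
    frame = pd.DataFrame({
        "contig": ["Scer_acc_MPR1"] * 4 + ["Scer_chrI"],
        "species": ["Scer"] * 5,
        "kind": ["accessory"] * 4 + ["chromosome"],
        "start": [0, 5_000, 10_000, 15_000, 0],
        "end": [10_000, 15_000, 20_000, 25_000, 10_000],
        "depth": [30, 30, 0, 0, 30],
        "reads": [3000, 3000, 0, 0, 3000],
        "masked": [False, False, True, True, False],
        "norm": [1.0, 1.0, np.nan, np.nan, 1.0]})
    prof = cov.CoverageProfile("s", frame, 30.0, 10_000, 5_000)
    call = cov.call_accessory(prof, "MPR1", min_breadth=0.5)
    assert call.present and call.breadth == 0.5


def test_unknown_locus_errors(trio):
    pop, depth = trio
    with pytest.raises(KeyError, match="nonesuch"):
        cov.call_accessory(_profile(pop, depth, "F01"), "nonesuch")


def test_marker_cooccurrence_reproduces_planted_rates():
    """90% planted wine-circle concordance in a wine clade is recovered."""
    rng = np.random.default_rng(0)
    strains = [f"s{i}" for i in range(200)]
    clade_of = {s: ("wine" if i < 120 else "other")
                for i, s in enumerate(strains)}
    rows = []
    for s in strains:
        in_wine = clade_of[s] == "wine"
        carries = rng.random() < (0.9 if in_wine else 0.1)
        rows.append((s, "wine_circle", carries, 1.0, 1.0))
        rows.append((s, "RTM1_cluster", not in_wine, 1.0, 1.0))
    calls = pd.DataFrame(rows, columns=["strain", "locus", "present",
                                        "breadth", "mean_norm_depth"])
    out = cov.marker_profile(calls, ["wine_circle", "RTM1_cluster"],
                             clade_of, "wine")
    co = out["co_occurrence"].set_index("locus")
    wc = co.loc["wine_circle"]
    rate = wc["carriers_in_clade"] / 120
    assert abs(rate - 0.9) < 4 * np.sqrt(0.9 * 0.1 / 120)
    both = out["carriers_of_all"]
    assert all(clade_of[s] != "wine" for s in both)  # interclade carriers


def test_empty_marker_set_gives_empty_summary():
    out = cov.marker_profile(pd.DataFrame(columns=["strain", "locus",
                                                   "present"]), [])
    assert out["presence"].empty and out["co_occurrence"].empty
    assert out["carriers_of_all"] == []
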