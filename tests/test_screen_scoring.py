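"""Spacer extraction, member counting, fitness computation, and hit calling."""

import numpy as np
import pandas as pd
import pytest

from crisprikit.fixtures import ScreenSimSpec, render_fastq, simulate_manifest, simulate_screen
from crisprikit.screen_scoring import (
    LibraryManifest,
    SampleSheet,
    aggregate_srna,
    count_members,
    cpm,
    extract_spacer,
    guide_log2fc,
    score_screen,
)
from crisprikit.sequence_model import revcomp

F5 = "ATTTCTACTGTTGTAGAT"
F3 = "GTCGACCTGCAGGCATGC"


def _read_for(spacer, pad5="ACGT" * 5, pad3="TGCA" * 10):
    return pad5 + F5 + spacer + F3 + pad3


class TestExtractSpacer:
    def test_embedded_spacer_recovered(self):
        spacer = "ACGTACGTGGCCAACGTTGA"
        assert extract_spacer((_read_for(spacer), None), F5, F3) == spacer

    def test_reverse_complement_read_recovered(self):
        spacer = "ACGTACGTGGCCAACGTTGA"
        assert extract_spacer((revcomp(_read_for(spacer)), None), F5, F3) == spacer

    def test_spacer_found_in_mate_when_first_read_misses(self):
        spacer = "ACGTACGTGGCCAACGTTGA"
        assert extract_spacer(("A" * 60, _read_for(spacer)), F5, F3) == spacer

    def test_one_flank_mismatch_tolerated_two_rejected(self):
        spacer = "ACGTACGTGGCCAACGTTGA"
        f5_1mm = "C" + F5[1:]
        f5_2mm = "CC" + F5[2:]
        assert extract_spacer(
            ("AA" + f5_1mm + spacer + F3 + "AA", None), F5, F3, max_flank_mismatch=1
        ) == spacer
        assert (
            extract_spacer(
                ("AA" + f5_2mm + spacer + F3 + "AA", None), F5, F3, max_flank_mismatch=1
            )
            is None
        )

    def test_implausible_length_rejected(self):
        assert extract_spacer((_read_for("ACGT"), None), F5, F3) is None


def _manifest3():
    return LibraryManifest(
        {
            "m1": {"type": "gRNA", "spacers": ["ACGTACGTGGCCAACGTTGA"], "gene_id": "gA"},
            "m2": {"type": "gRNA", "spacers": ["TTGGCCAAGGTTCCAAGGCC"], "gene_id": "gA"},
            "m3": {"type": "gRNA", "spacers": ["GATCGATCGGATCCGATCGA"], "gene_id": "gB"},
        }
    )


def test_manifest_rejects_shared_spacers():
    with pytest.raises(ValueError, match="shared"):
        LibraryManifest(
            {
                "m1": {"type": "gRNA", "spacers": ["ACGT" * 5], "gene_id": "gA"},
                "m2": {"type": "gRNA", "spacers": ["ACGT" * 5], "gene_id": "gB"},
            }
        )


def test_count_members_exact_composition(tmp_path):
    manifest = _manifest3()
    composition = {"m1": 5, "m2": 3, "m3": 2}
    counts_in = pd.Series(composition)
    mtab = pd.DataFrame(
        {
            "member_id": list(manifest.members),
            "spacers": [manifest.members[m]["spacers"][0] for m in manifest.members],
        }
    )
    r1, r2 = tmp_path / "s1_R1.fastq", tmp_path / "s1_R2.fastq"
    render_fastq(counts_in, mtab, (F5, F3), r1, r2, seed=3)
    counts, stats = count_members({"s1": (r1, r2)}, manifest, (F5, F3))
    assert counts["s1"].to_dict() == composition
    assert stats.loc["s1", "matched"] == 10
    assert stats.loc["s1", "unmatched"] == 0


def test_count_members_logs_unmatched(tmp_path):
    manifest = _manifest3()
    r1 = tmp_path / "r1.fastq"
    # one matching read + one read with an unknown spacer
    good = _read_for("ACGTACGTGGCCAACGTTGA")
    bad = _read_for("AAAACCCCGGGGTTTTAAAA")
    r1.write_text(f"@a\n{good}\n+\n{'I' * len(good)}\n@b\n{bad}\n+\n{'I' * len(bad)}\n")
    counts, stats = count_members({"s": (r1, None)}, manifest, (F5, F3))
    assert counts["s"].sum() == 1
    assert stats.loc["s", "unmatched"] == 1


def _sheet(reps=1):
    return SampleSheet(
        {
            **{f"control_{r}": ("control", r) for r in range(1, reps + 1)},
            **{f"stress_{r}": ("stress", r) for r in range(1, reps + 1)},
        }
    )


def test_log2fc_identical_counts_is_zero():
    counts = pd.DataFrame({"control_1": [100, 50], "stress_1": [100, 50]},
                          index=["m1", "m2"])
    fit = guide_log2fc(counts, _sheet())
    assert np.allclose(fit["mean_log2fc"], 0.0)


def test_log2fc_doubling_is_one():
    # equal depth: second member balances the totals
    counts = pd.DataFrame({"control_1": [100, 300], "stress_1": [200, 200]},
                          index=["m1", "m2"])
    fit = guide_log2fc(counts, _sheet(), pseudocount=1e-9)
    assert fit.loc["m1", "mean_log2fc"] == pytest.approx(1.0, abs=1e-6)


def test_log2fc_zero_control_with_pseudocount():
    """At depth 1e6 the CPM factor is 1, so 0 vs 10 gives log2(10.5/0.5)."""
    n = 1_000_000
    counts = pd.DataFrame(
        {"control_1": [0, n], "stress_1": [10, n - 10]}, index=["m1", "m2"]
    )
    fit = guide_log2fc(counts, _sheet(), pseudocount=0.5)
    assert fit.loc["m1", "rep1"] == pytest.approx(np.log2(21), abs=1e-6)


def test_log2fc_scaling_invariance():
    """Multiplying one sample's counts by a constant changes nothing (CPM)."""
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        {
            "control_1": rng.integers(1, 1000, 50),
            "stress_1": rng.integers(1, 1000, 50),
        },
        index=[f"m{i}" for i in range(50)],
    )
    fit1 = guide_log2fc(counts, _sheet())
    scaled = counts.copy()
    scaled["stress_1"] *= 17
    fit2 = guide_log2fc(scaled, _sheet())
    assert np.allclose(fit1["rep1"], fit2["rep1"])


def test_zero_total_sample_errors():
    counts = pd.DataFrame({"control_1": [0, 0], "stress_1": [1, 1]}, index=["a", "b"])
    with pytest.raises(ValueError, match="zero total"):
        cpm(counts)


def test_aggregate_mean_and_thresholds():
    def spacer(i):  # unique 20-mers: index written in base 4
        digits = np.base_repr(i, base=4).zfill(4)
        return "ACGT" * 4 + "".join("ACGT"[int(d)] for d in digits)

    manifest = LibraryManifest(
        {
            f"m{i}": {"type": "gRNA", "spacers": [spacer(i)], "gene_id": g}
            for i, g in enumerate(["gA"] * 3 + ["gB"] * 3 + ["gC"] * 3)
        }
    )
    rng = np.random.default_rng(42)
    rep_cols = ["rep1", "rep2", "rep3"]
    rows = {}
    for i, g in enumerate(["gA"] * 3 + ["gB"] * 3 + ["gC"] * 3):
        shift = {"gA": 1.0, "gB": -0.7, "gC": 0.4}[g]
        rows[f"m{i}"] = rng.normal(shift, 0.05, 3)
    fit = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    fit.columns = rep_cols
    fit["mean_log2fc"] = fit[rep_cols].mean(axis=1)
    res = aggregate_srna(fit, manifest)
    assert res.loc["gA", "hit"] and res.loc["gA", "direction"] == "enriched"
    assert res.loc["gB", "hit"] and res.loc["gB", "direction"] == "depleted"
    # |mean| < 0.5: never a hit regardless of FDR
    assert not res.loc["gC", "hit"]
    # unweighted mean over members
    assert res.loc["gA", "mean_log2fc"] == pytest.approx(
        fit.loc[["m0", "m1", "m2"], "mean_log2fc"].mean()
    )


def test_sign_convention_enrichment_positive():
    """Members enriched under stress must get positive log2FC."""
    counts = pd.DataFrame({"control_1": [100, 900], "stress_1": [400, 600]},
                          index=["up", "down"])
    fit = guide_log2fc(counts, _sheet())
    assert fit.loc["up", "mean_log2fc"] > 0 > fit.loc["down", "mean_log2fc"]


def test_simulated_screen_recovers_planted_effects():
    effects = {"srna_0000": 1.5, "srna_0001": -1.5}
    spec = ScreenSimSpec(seed=11, n_genes=30, effects=effects)
    counts, sheet_df, truth = simulate_screen(spec)
    manifest = LibraryManifest(
        {
            row.member_id: {"type": "gRNA", "spacers": [row.spacers],
                            "gene_id": row.gene_id}
            for row in simulate_manifest(spec).itertuples()
        }
    )
    sheet = SampleSheet(
        {r.sample_id: (r.condition, int(r.replicate)) for r in sheet_df.itertuples()}
    )
    fit, srna = score_screen(counts, sheet, manifest)
    for gene, lfc in effects.items():
        assert srna.loc[gene, "hit"]
        assert np.sign(srna.loc[gene, "mean_log2fc"]) == np.sign(lfc)


def test_permuted_labels_control_false_positives():
    """Swapping condition labels destroys planted effects' directionality; the
    hit rate on null genes stays near the nominal FDR."""
    spec = ScreenSimSpec(seed=5, n_genes=50)
    counts, sheet_df, _ = simulate_screen(spec)
    manifest = LibraryManifest(
        {
            row.member_id: {"type": "gRNA", "spacers": [row.spacers],
                            "gene_id": row.gene_id}
            for row in simulate_manifest(spec).itertuples()
        }
    )
    sheet = SampleSheet(
        {r.sample_id: (r.condition, int(r.replicate)) for r in sheet_df.itertuples()}
    )
    _, srna = score_screen(counts, sheet, manifest)
    assert srna["hit"].mean() <= 0.08
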