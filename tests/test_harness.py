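"""File parsing, validation, scoring, leaderboards, patch error analysis."""

import numpy as np
import pytest

from cellscore import (
    InputValidationError,
    MetricResult,
    ReferenceSet,
    ScoredSubmission,
    SubmissionFormatError,
    build_leaderboard,
    icc_2_1,
    interrater_avg_icc,
    interrater_avg_pk,
    load_submission,
    parse_reference,
    patch_mse,
    prediction_probability,
    score_submission,
    significance_frontier,
    validate_submission,
    write_reference,
)

from conftest import submission_from, toy_reference


def write_submission(path, rows, header="patch_id,score"):
    lines = [header] + rows
    path.write_text("\n".join(lines) + "\n")
    return path


def make_metric(value):
    return MetricResult(
        value=value, ci_low=value - 0.01, ci_high=value + 0.01,
        level=0.95, n_boot=10, n_dropped=0, seed=0, per_rater={"path1": value},
    )


def make_entry(entry_id, pk):
    return ScoredSubmission(
        team=entry_id, entry_id=entry_id, avg_pk=make_metric(pk),
        avg_icc=make_metric(pk),
    )


# ---------------------------------------------------------------------------
# reference I/O


def test_reference_roundtrip(tmp_path):
    ref = toy_reference()
    path = tmp_path / "reference.csv"
    write_reference(ref, path)
    back = parse_reference(path)
    assert list(back.patch_ids) == list(ref.patch_ids)
    assert list(back.case_ids) == list(ref.case_ids)
    assert back.rater_ids == ref.rater_ids
    for r in ref.rater_ids:
        np.testing.assert_allclose(back.scores[r], ref.scores[r], atol=1e-12)


def test_percent_unit_column_normalized(tmp_path):
    path = tmp_path / "ref.csv"
    path.write_text(
        "patch_id,slide_id,case_id,path1:percent,path2\n"
        "p1,s1,c1,90,0.8\n"
        "p2,s1,c1,45,0.5\n"
    )
    ref = parse_reference(path)
    np.testing.assert_allclose(ref.scores["path1"], [0.9, 0.45])
    np.testing.assert_allclose(ref.scores["path2"], [0.8, 0.5])


def test_duplicate_patch_id_names_id_and_line(tmp_path):
    path = tmp_path / "ref.csv"
    path.write_text(
        "patch_id,slide_id,case_id,path1\np1,s1,c1,0.5\np1,s1,c1,0.6\n"
    )
    with pytest.raises(InputValidationError, match=r"p1.*line 3"):
        parse_reference(path)


def test_reference_score_out_of_range_rejected(tmp_path):
    path = tmp_path / "ref.csv"
    path.write_text("patch_id,slide_id,case_id,path1\np1,s1,c1,1.5\np2,s1,c1,0.5\n")
    with pytest.raises(InputValidationError, match="outside"):
        parse_reference(path)


def test_reference_missing_rater_cell_rejected(tmp_path):
    path = tmp_path / "ref.csv"
    path.write_text("patch_id,slide_id,case_id,path1\np1,s1,c1,\np2,s1,c1,0.5\n")
    with pytest.raises(InputValidationError, match="missing"):
        parse_reference(path)


# ---------------------------------------------------------------------------
# submission validation


def test_complete_submission_is_valid(tmp_path, small_ref):
    rows = [f"{p},0.5" for p in small_ref.patch_ids]
    report = validate_submission(write_submission(tmp_path / "s.csv", rows), small_ref)
    assert report.valid
    assert report.summary() == "valid"


def test_missing_patch_reported(tmp_path, small_ref):
    rows = [f"{p},0.5" for p in list(small_ref.patch_ids)[:-1]]
    report = validate_submission(write_submission(tmp_path / "s.csv", rows), small_ref)
    assert not report.valid
    assert report.missing_patches == (str(small_ref.patch_ids[-1]),)
    assert report.extra_patches == ()


def test_out_of_range_and_malformed_and_extra_rows_reported(tmp_path, small_ref):
    rows = [f"{p},0.5" for p in small_ref.patch_ids]
    rows[0] = f"{small_ref.patch_ids[0]},1.2"          # out of range
    rows[1] = f"{small_ref.patch_ids[1]},abc"          # not a number
    rows.append("ghost_patch,0.4")                     # unknown patch
    rows.append(f"{small_ref.patch_ids[2]},0.5,extra")  # wrong column count
    report = validate_submission(write_submission(tmp_path / "s.csv", rows), small_ref)
    assert not report.valid
    assert report.out_of_range == (str(small_ref.patch_ids[0]),)
    assert str(small_ref.patch_ids[1]) in report.missing_patches
    assert report.extra_patches == ("ghost_patch",)
    reasons = [reason for _, reason in report.malformed_rows]
    assert any("not a number" in r for r in reasons)
    assert any("2 columns" in r for r in reasons)


def test_validation_is_nondestructive_but_loading_is_strict(tmp_path, small_ref):
    path = write_submission(tmp_path / "s.csv", ["p00,0.5"])
    report = validate_submission(path, small_ref)  # no exception
    assert not report.valid
    with pytest.raises(SubmissionFormatError):
        load_submission(path, team="t", entry_id="e", ref=small_ref)


def test_crlf_and_utf8_bom_accepted(tmp_path, small_ref):
    body = "\r\n".join(
        ["patch_id,score"] + [f"{p},0.25" for p in small_ref.patch_ids]
    )
    path = tmp_path / "s.csv"
    path.write_bytes(b"\xef\xbb\xbf" + body.encode())
    assert validate_submission(path, small_ref).valid


# ---------------------------------------------------------------------------
# scoring


def test_scoring_clone_of_rater1(small_ref):
    sub = submission_from(small_ref, small_ref.scores["path1"])
    scored = score_submission(sub, small_ref, n_boot=20, seed=0)
    assert scored.avg_pk.per_rater["path1"] == 1.0
    interrater = prediction_probability(
        small_ref.scores["path2"], small_ref.scores["path1"]
    )
    assert scored.avg_pk.value == pytest.approx((1.0 + interrater) / 2, abs=1e-15)


def test_constant_submission_scores_half(small_ref):
    sub = submission_from(small_ref, np.full(small_ref.n_patches, 0.3))
    scored = score_submission(sub, small_ref, n_boot=20, seed=0)
    assert scored.avg_pk.value == 0.5


def test_monotone_distortion_keeps_pk_drops_icc(small_ref):
    base = small_ref.scores["path1"]
    identity = submission_from(small_ref, base, entry_id="id")
    distorted = submission_from(small_ref, base**3, entry_id="cubed")
    s_id = score_submission(identity, small_ref, n_boot=10, seed=0)
    s_di = score_submission(distorted, small_ref, n_boot=10, seed=0)
    assert s_di.avg_pk.value == pytest.approx(s_id.avg_pk.value, abs=0)
    assert s_di.avg_icc.value < s_id.avg_icc.value


def test_scoring_invariant_under_patch_order(small_ref):
    perm = np.random.default_rng(1).permutation(small_ref.n_patches)
    shuffled = small_ref.take(perm)
    sub = submission_from(small_ref, np.linspace(0.1, 0.9, small_ref.n_patches))
    a = score_submission(sub, small_ref, n_boot=5, seed=0)
    b = score_submission(sub, shuffled, n_boot=5, seed=0)
    assert a.avg_pk.value == pytest.approx(b.avg_pk.value, abs=1e-12)
    assert a.avg_icc.value == pytest.approx(b.avg_icc.value, abs=1e-12)


def test_interrater_summaries(small_ref):
    pk = interrater_avg_pk(small_ref)
    fwd = prediction_probability(small_ref.scores["path1"], small_ref.scores["path2"])
    rev = prediction_probability(small_ref.scores["path2"], small_ref.scores["path1"])
    assert pk == pytest.approx((fwd + rev) / 2, abs=1e-15)
    icc = interrater_avg_icc(small_ref)
    assert icc == pytest.approx(
        icc_2_1(np.column_stack([small_ref.scores["path1"], small_ref.scores["path2"]])),
        abs=1e-15,
    )


# ---------------------------------------------------------------------------
# leaderboard and frontier


def test_competition_ranking():
    entries = [make_entry(e, v) for e, v in
               [("a", 0.9), ("b", 0.8), ("c", 0.8), ("d", 0.7)]]
    rows = build_leaderboard(entries)
    assert [r.rank for r in rows] == [1, 2, 2, 4]
    assert [r.entry_id for r in rows] == ["a", "b", "c", "d"]


def test_single_entry_and_permutation_invariance():
    assert build_leaderboard([make_entry("x", 0.5)])[0].rank == 1
    entries = [make_entry(e, v) for e, v in
               [("a", 0.7), ("b", 0.9), ("c", 0.8)]]
    fwd = build_leaderboard(entries)
    rev = build_leaderboard(entries[::-1])
    assert [r.entry_id for r in fwd] == [r.entry_id for r in rev] == ["b", "c", "a"]


def test_frontier_flags_first_significantly_worse_entry():
    from cellscore import SyntheticConfig, generate_reference

    cfg = SyntheticConfig(n_patients=30, slides_per_patient=1, patches_per_slide=10)
    lref = generate_reference(cfg, seed=17)
    ref = lref.reference
    rng = np.random.default_rng(18)
    subs = {
        "clone": submission_from(ref, lref.latent, entry_id="clone"),
        "noisy1": submission_from(
            ref, np.clip(lref.latent + rng.normal(0, 0.4, ref.n_patches), 0, 1),
            entry_id="noisy1"),
        "noisy2": submission_from(
            ref, np.clip(lref.latent + rng.normal(0, 0.4, ref.n_patches), 0, 1),
            entry_id="noisy2"),
    }
    scored = [score_submission(s, ref, n_boot=10, seed=0) for s in subs.values()]
    rows = build_leaderboard(scored)
    assert rows[0].entry_id == "clone"
    frontier = significance_frontier(rows, ref, subs, n_boot=200, seed=1)
    assert frontier["clone"] == rows[1].entry_id


def test_frontier_empty_for_identical_entries(small_ref):
    values = np.linspace(0.05, 0.95, small_ref.n_patches)
    subs = {e: submission_from(small_ref, values, entry_id=e) for e in ("a", "b", "c")}
    scored = [score_submission(s, small_ref, n_boot=10, seed=0) for s in subs.values()]
    rows = build_leaderboard(scored)
    frontier = significance_frontier(rows, small_ref, subs, n_boot=50, seed=2)
    assert all(v is None for v in frontier.values())


# ---------------------------------------------------------------------------
# patch-level error analysis


def test_patch_mse_hand_example():
    ref = ReferenceSet.validated(
        patch_ids=["p1", "p2"],
        slide_ids=["s", "s"],
        case_ids=["c", "c"],
        scores={"path1": [0.5, 0.1], "path2": [0.5, 0.1]},
    )
    subs = [
        submission_from(ref, [0.4, 0.1], entry_id="a"),
        submission_from(ref, [0.6, 0.1], entry_id="b"),
    ]
    errors = {e.patch_id: e for e in patch_mse(subs, ref)}
    assert errors["p1"].mse == pytest.approx(0.01, abs=1e-15)
    assert errors["p2"].mse == 0.0
    assert errors["p1"].avg_score == pytest.approx(0.5)
    assert errors["p1"].sd_score == pytest.approx(0.1)


def test_patch_mse_identity_when_raters_agree(small_ref):
    # both raters scoring s makes MSE == (avg - s)^2 + population variance
    rng = np.random.default_rng(23)
    s = rng.random(small_ref.n_patches)
    ref = ReferenceSet.validated(
        patch_ids=list(map(str, small_ref.patch_ids)),
        slide_ids=list(map(str, small_ref.slide_ids)),
        case_ids=list(map(str, small_ref.case_ids)),
        scores={"path1": s, "path2": s},
    )
    mat = rng.random((small_ref.n_patches, 5))
    subs = [submission_from(ref, mat[:, j], entry_id=f"a{j}") for j in range(5)]
    by_id = {e.patch_id: e for e in patch_mse(subs, ref)}
    for i, pid in enumerate(map(str, ref.patch_ids)):
        e = by_id[pid]
        expected = (e.avg_score - s[i]) ** 2 + np.var(mat[i])
        assert e.mse == pytest.approx(expected, abs=1e-12)


def test_patch_mse_sorted_descending(small_ref):
    rng = np.random.default_rng(24)
    subs = [
        submission_from(small_ref, rng.random(small_ref.n_patches), entry_id=f"a{j}")
        for j in range(3)
    ]
    errors = patch_mse(subs, small_ref)
    mses = [e.mse for e in errors]
    assert mses == sorted(mses, reverse=True)
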