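"""Fusion layers: block assembly, OC-SVM thresholding, SIMCA, HLDF, pipelines."""

import dataclasses

import numpy as np
import pytest

from chemfuse.core import FeatureBlock, Sample, SensorPosition, ValidationError
from chemfuse.fusion import (
    HLDFPipeline,
    IMSOneClassPipeline,
    LLDFPipeline,
    MLDFPipeline,
    SimcaPipeline,
    build_fusion_dataset,
    fuse,
    hldf_combine,
    lldf_assemble,
    load_pipeline,
    mldf_assemble,
    ocsvm_classify,
    ocsvm_fit,
    pca_blocks_fit,
    pca_blocks_transform,
    save_pipeline,
    simca_classify,
    simca_fit,
)
from chemfuse.positioning import GateRefusalError
from chemfuse.preprocess import autoscale_apply, autoscale_fit, snv_block
from chemfuse.synth import default_templates, generate_scene


# ---------------------------------------------------------------------------
# Block assembly and provenance
# ---------------------------------------------------------------------------

def _preprocessed(corpus):
    ims = autoscale_apply(corpus.blocks["ims"], autoscale_fit(corpus.blocks["ims"]))
    qepas = snv_block(corpus.blocks["qepas"])
    return ims, qepas


def test_lldf_assemble_shape_and_provenance(dmmp_corpus):
    ims, qepas = _preprocessed(dmmp_corpus)
    rt = dmmp_corpus.blocks["rt"].matrix[:, 0]
    out = lldf_assemble(ims, qepas, rt)
    assert out.n_samples == 40
    assert out.n_variables == ims.n_variables + qepas.n_variables + 1
    assert np.allclose(out.matrix[:, -1], rt)  # raw trailing RT column
    assert "concat(ims|qepas|rt)" in out.provenance


def test_lldf_assemble_enforces_preprocessing(dmmp_corpus):
    ims, qepas = _preprocessed(dmmp_corpus)
    rt = dmmp_corpus.blocks["rt"].matrix[:, 0]
    with pytest.raises(ValidationError):
        lldf_assemble(dmmp_corpus.blocks["ims"], qepas, rt)  # not autoscaled
    with pytest.raises(ValidationError):
        lldf_assemble(ims, dmmp_corpus.blocks["qepas"], rt)  # not SNV


def test_mldf_assemble_scores_plus_rt(dmmp_corpus):
    ims, qepas = _preprocessed(dmmp_corpus)
    rt = dmmp_corpus.blocks["rt"].matrix[:, 0]
    pca = pca_blocks_fit({"ims": ims, "qepas": qepas})
    out = mldf_assemble(ims, qepas, rt, pca)
    m = pca.blocks["ims"].n_retained + pca.blocks["qepas"].n_retained
    assert out.n_variables == m + 1
    assert np.allclose(out.matrix[:, -1], rt)


def test_pca_blocks_ev_criterion_and_block_scaling(dmmp_corpus):
    ims, qepas = _preprocessed(dmmp_corpus)
    pca = pca_blocks_fit({"ims": ims, "qepas": qepas}, ev=0.99)
    scores = pca_blocks_transform(pca, {"ims": ims, "qepas": qepas})
    for name, block in (("ims", ims), ("qepas", qepas)):
        sub = pca.blocks[name]
        # smallest component count reaching 99% cumulative EV
        cum = np.cumsum(sub.explained_variance_ratio)
        assert cum[sub.n_retained - 1] >= 0.99 - 1e-12
        assert sub.n_retained == 1 or cum[sub.n_retained - 2] < 0.99
        # block scaling: total training score variance is 1 per block
        total = scores[name].var(axis=0, ddof=1).sum()
        assert total == pytest.approx(1.0, rel=1e-9)


def test_pca_blocks_validation(dmmp_corpus):
    ims, _ = _preprocessed(dmmp_corpus)
    with pytest.raises(ValidationError):
        pca_blocks_fit({"ims": ims}, ev=0.0)
    with pytest.raises(ValidationError):
        pca_blocks_fit({"ims": FeatureBlock("ims", ims.matrix[:1])})


# ---------------------------------------------------------------------------
# One-class SVM with decision-threshold override
# ---------------------------------------------------------------------------

def _tight_cluster(n=30, d=4, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 0.05, size=(n, d)) + np.array([3.0, 1.0, -2.0, 0.5])


def test_ocsvm_training_decisions_mostly_positive():
    model = ocsvm_fit(_tight_cluster())
    assert np.all(np.isfinite(model.training_decisions))
    assert (model.training_decisions >= 0).mean() > 0.5


def test_ocsvm_deterministic_refit():
    X = _tight_cluster(seed=3)
    m1, m2 = ocsvm_fit(X), ocsvm_fit(X)
    assert np.array_equal(m1.training_decisions, m2.training_decisions)


def test_ocsvm_reapplication_matches_training_decisions():
    X = _tight_cluster(seed=5)
    model = ocsvm_fit(X)
    f, _ = ocsvm_classify(model, X)
    assert np.allclose(f, model.training_decisions)


def test_ocsvm_threshold_rule_and_single_sample():
    X = _tight_cluster()
    model = ocsvm_fit(X, threshold=0.0)
    f, inlier = ocsvm_classify(model, X[0])
    assert isinstance(f, float) and isinstance(inlier, bool)
    assert inlier == (f >= 0.0)
    # a linear one-class boundary is a half-space: points on the origin
    # side of the training cluster fall below it
    f_out, inlier_out = ocsvm_classify(model, np.zeros(4))
    assert f_out < 0 and not inlier_out


def test_ocsvm_threshold_monotonicity():
    X = _tight_cluster(seed=7)
    rng = np.random.default_rng(8)
    probes = X + rng.normal(0.0, 0.2, size=X.shape)
    model = ocsvm_fit(X)
    f, _ = ocsvm_classify(model, probes)
    for lo, hi in [(-1.0, 0.0), (0.0, 0.5), (-0.25, 0.25)]:
        pos_hi = f >= hi
        pos_lo = f >= lo
        # lowering tau never converts a positive to a negative
        assert np.all(pos_lo[pos_hi])


def test_ocsvm_validation():
    with pytest.raises(ValidationError):
        ocsvm_fit(np.ones((1, 3)))
    with pytest.raises(ValidationError):
        ocsvm_fit(np.array([[1.0, np.nan]] * 3))
    with pytest.raises(ValidationError):
        ocsvm_fit(_tight_cluster(), kernel="cubic")
    model = ocsvm_fit(_tight_cluster())
    with pytest.raises(ValidationError):
        ocsvm_classify(model, np.ones((2, 7)))


# ---------------------------------------------------------------------------
# SIMCA
# ---------------------------------------------------------------------------

def _simca_brute_force(model, X):
    """Explicit projection + distance loops (oracle for simca_classify)."""
    dE, dM = [], []
    for row in np.atleast_2d(X):
        centred = row - model.mean
        t = [float(centred @ model.loadings[j]) for j in range(model.n_components)]
        e2 = m2 = 0.0
        for j, tj in enumerate(t):
            delta = tj - model.centroid[j]
            e2 += delta**2
            m2 += (delta / model.score_sds[j]) ** 2
        dE.append(np.sqrt(e2))
        dM.append(np.sqrt(m2))
    return np.array(dE), np.array(dM)


def test_simca_against_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(4, 12))
        d = int(rng.integers(2, 8))
        m = int(rng.integers(1, min(n - 1, d) + 1))
        X = rng.normal(size=(n, d)) * rng.uniform(0.5, 3.0, size=d)
        model = simca_fit(X, n_components=m)
        probes = rng.normal(size=(5, d))
        dE, dM, _ = simca_classify(model, probes)
        dE_ref, dM_ref = _simca_brute_force(model, probes)
        assert np.allclose(dE, dE_ref, atol=1e-9, rtol=0.0)
        assert np.allclose(dM, dM_ref, atol=1e-9, rtol=0.0)


def test_simca_accepts_class_rejects_far():
    rng = np.random.default_rng(1)
    X = rng.normal(0.0, 1.0, size=(30, 5))
    model = simca_fit(X, n_components=3)
    _, _, pos = simca_classify(model, X)
    assert pos.mean() > 0.9
    _, _, far = simca_classify(model, np.full(5, 50.0))
    assert not far


def test_simca_limit_monotonicity():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 4))
    model = simca_fit(X, n_components=2, dE_max=1.0, dM_max=1.0)
    probes = rng.normal(size=(50, 4))
    _, _, tight = simca_classify(model, probes)
    wider = dataclasses.replace(model, dE_max=2.0, dM_max=2.0)
    _, _, loose = simca_classify(wider, probes)
    # raising the limits never converts a positive to a negative
    assert np.all(loose[tight])


def test_simca_validation():
    rng = np.random.default_rng(3)
    with pytest.raises(ValidationError):
        simca_fit(rng.normal(size=(2, 4)))  # < 3 samples
    with pytest.raises(ValidationError):
        simca_fit(rng.normal(size=(5, 4)), n_components=5)
    with pytest.raises(ValidationError):
        simca_fit(np.ones((5, 4)))  # zero variance
    model = simca_fit(rng.normal(size=(6, 4)), n_components=2)
    with pytest.raises(ValidationError):
        simca_classify(model, np.ones(3))


def test_simca_fit_from_labelled_dataset(tatp_corpus):
    model = simca_fit(tatp_corpus, class_label="tatp")
    width = tatp_corpus.blocks["qepas"].n_variables + 1
    assert model.mean.size == width
    with pytest.raises(ValidationError):
        simca_fit(tatp_corpus)  # class_label required


# ---------------------------------------------------------------------------
# HLDF combination rule
# ---------------------------------------------------------------------------

def test_hldf_combine_any_all():
    ims_pos, ims_neg = (0.4, True), (-0.2, False)
    gc_pos, gc_neg = (1.0, 2.0, True), (9.0, 9.0, False)
    assert hldf_combine(ims_pos, gc_neg, rule="any").positive
    assert hldf_combine(ims_neg, gc_pos, rule="any").positive
    assert not hldf_combine(ims_neg, gc_neg, rule="any").positive
    assert not hldf_combine(ims_pos, gc_neg, rule="all").positive
    assert hldf_combine(ims_pos, gc_pos, rule="all").positive


def test_hldf_combine_validation():
    with pytest.raises(ValidationError):
        hldf_combine((0.1, True), (1.0, 1.0, True), rule="majority")
    with pytest.raises(ValidationError):
        hldf_combine(None, (1.0, 1.0, True))


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

def test_lldf_pipeline_accepts_targets_rejects_below_boundary(dmmp_corpus, mixed_corpus):
    """LLDF target acceptance, and rejection on the bounded side.

    A linear one-class decision function bounds the class from below
    along the weight direction only, so rejection power is one-sided:
    analytes whose raw features (notably retention time) fall short of
    the target's are rejected, while samples that overshoot in every
    coordinate are not.  Cross-analyte specificity is the job of the
    sequential GC-QEPAS identification, not of the one-class monitors.
    """
    pipe = LLDFPipeline("dmmp").fit(dmmp_corpus)
    pos, evidence = pipe.predict(dmmp_corpus)
    assert pos.mean() > 0.9  # training rows are essentially all inside
    acetone = mixed_corpus.subset(np.flatnonzero(mixed_corpus.labels == "acetone"))
    pos_other, ev_other = pipe.predict(acetone)
    assert not pos_other.any()
    assert np.all(ev_other["decision_function"] < 0)
    assert evidence["decision_function"].shape == (40,)


def test_mldf_pipeline_runs_and_rejects_below_boundary(dmmp_corpus, mixed_corpus):
    pipe = MLDFPipeline("dmmp", threshold=-0.02).fit(dmmp_corpus)
    pos, _ = pipe.predict(dmmp_corpus)
    assert pos.mean() > 0.9
    acetone = mixed_corpus.subset(np.flatnonzero(mixed_corpus.labels == "acetone"))
    pos_other, _ = pipe.predict(acetone)
    assert not pos_other.any()


def test_hldf_pipeline_branches_and_rule(tatp_corpus, mixed_corpus):
    pipe = HLDFPipeline("tatp").fit(tatp_corpus)
    pos, evidence = pipe.predict(tatp_corpus)
    assert pos.mean() > 0.9
    assert set(evidence) >= {"ims_decision_function", "gc_dE", "gc_dM", "rule"}
    other = mixed_corpus.subset(np.flatnonzero(mixed_corpus.labels != "tatp"))
    pos_other, _ = pipe.predict(other)
    assert not pos_other.any()


def test_pipeline_requires_fit_before_predict(dmmp_corpus):
    with pytest.raises(ValidationError):
        LLDFPipeline("dmmp").predict(dmmp_corpus)
    with pytest.raises(ValidationError):
        SimcaPipeline("dmmp").predict(dmmp_corpus)
    with pytest.raises(ValidationError):
        LLDFPipeline("missing-analyte").fit(dmmp_corpus)


def test_save_load_round_trip(tmp_path, tatp_corpus):
    pipe = HLDFPipeline("tatp").fit(tatp_corpus)
    path = tmp_path / "tatp.joblib"
    save_pipeline(pipe, path)
    back = load_pipeline(path)
    pos1, ev1 = pipe.predict(tatp_corpus)
    pos2, ev2 = back.predict(tatp_corpus)
    assert np.array_equal(pos1, pos2)
    assert np.allclose(ev1["ims_decision_function"], ev2["ims_decision_function"])


# ---------------------------------------------------------------------------
# Gated end-to-end fusion
# ---------------------------------------------------------------------------

def _scene_pair(separation_m, seed=21):
    templates = default_templates()
    samples = generate_scene(
        [(templates["tatp"], 50.0)],
        ims_position=SensorPosition(0.0, 0.0, 0.0),
        gc_position=SensorPosition(separation_m, 0.0, 0.0),
        seed=seed,
    )
    return samples[0].reading("IMS"), samples[0].reading("GCQEPAS")


def test_fuse_refuses_distant_sensors(tatp_corpus):
    pipe = HLDFPipeline("tatp").fit(tatp_corpus)
    ims, gc = _scene_pair(3.0)
    with pytest.raises(GateRefusalError) as err:
        fuse(ims, gc, pipe)
    assert not err.value.decision.fused


def test_fuse_identifies_colocated_target(tatp_corpus):
    pipe = HLDFPipeline("tatp").fit(tatp_corpus)
    ims, gc = _scene_pair(0.3)
    verdict = fuse(ims, gc, pipe)
    assert verdict.positive
    assert verdict.analyte == "tatp"
    assert verdict.gate.fused
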