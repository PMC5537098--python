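"""End-to-end semantic annotation: train per-term models, predict, report.

Given a cohort of lesion images and a table of visual-semantic-term (VST)
annotations, :func:`train` extracts the 496-dimensional feature matrix,
z-scores it, restricts the vocabulary to terms occurring in 20-75% of the
samples (rarer or near-universal terms give the selector too little
signal), runs the PmEI selector once per retained term, and refits a
Gaussian-kernel SVM on each term's selected features.  The resulting
:class:`ModelBundle` carries everything needed to annotate an unseen image
with :func:`predict` and to print the explicit feature-to-term mapping
with :func:`mapping_report`.  Bundles persist as a versioned JSON file.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import multiplicity as mp
from .feature_bank import (
    FeatureConfig,
    FeatureMatrix,
    apply_norm_stats,
    assemble_feature_vector,
    build_feature_matrix,
    feature_names,
    zscore_normalize,
)
from .image import LesionImage
from .pmei import BinaryAnnotation, PmeiResult, run_pmei

BUNDLE_FORMAT_VERSION = 1
MIN_OCCURRENCE = 0.20
MAX_OCCURRENCE = 0.75


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


@dataclass
class VSTAnnotationSet:
    """Sample-by-term presence table."""

    sample_ids: list[str]
    vocabulary: list[str]
    presence: np.ndarray  # bool, samples x terms

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, bool)
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("vocabulary terms must be unique")
        if self.presence.shape != (len(self.sample_ids), len(self.vocabulary)):
            raise ValueError("presence table shape does not match ids/vocabulary")
        if (~self.presence.any(axis=1)).any():
            missing = [
                s for s, row in zip(self.sample_ids, self.presence) if not row.any()
            ]
            raise ValueError(f"samples without any term: {missing}")

    def occurrence(self, term: str) -> float:
        j = self.vocabulary.index(term)
        return float(self.presence[:, j].mean())

    def binary_labels(self, term: str) -> BinaryAnnotation:
        j = self.vocabulary.index(term)
        labels = np.where(self.presence[:, j], 1, -1)
        return BinaryAnnotation(vst_name=term, labels=labels)

    # -- parsers ------------------------------------------------------------

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "VSTAnnotationSet":
        """Long format: one (sample_id, term) row per present term."""
        sid_col, term_col = df.columns[:2]
        samples = list(dict.fromkeys(df[sid_col].astype(str)))
        vocab = sorted(df[term_col].astype(str).unique())
        presence = np.zeros((len(samples), len(vocab)), bool)
        s_idx = {s: i for i, s in enumerate(samples)}
        t_idx = {t: j for j, t in enumerate(vocab)}
        for s, t in zip(df[sid_col].astype(str), df[term_col].astype(str)):
            presence[s_idx[s], t_idx[t]] = True
        return cls(sample_ids=samples, vocabulary=vocab, presence=presence)

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "VSTAnnotationSet":
        """Wide format: index = sample ids, one boolean/0-1 column per term."""
        return cls(
            sample_ids=[str(s) for s in df.index],
            vocabulary=[str(c) for c in df.columns],
            presence=df.to_numpy().astype(bool),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "VSTAnnotationSet":
        df = pd.read_csv(path, index_col=0)
        if df.shape[1] == 1:  # long: sample_id index + single term column
            return cls.from_long(df.reset_index())
        return cls.from_wide(df)


def filter_vsts(
    ann: VSTAnnotationSet,
    min_frac: float = MIN_OCCURRENCE,
    max_frac: float = MAX_OCCURRENCE,
) -> list[str]:
    """Terms whose occurrence fraction lies in [min_frac, max_frac] inclusive."""
    if not ann.sample_ids:
        raise ValueError("annotation set is empty")
    occ = ann.presence.mean(axis=0)
    kept = [t for t, o in zip(ann.vocabulary, occ) if min_frac <= o <= max_frac]
    if not kept:
        warnings.warn(
            f"no term has occurrence within [{min_frac:.0%}, {max_frac:.0%}]; "
            "the retained vocabulary is empty",
            stacklevel=2,
        )
    return kept


# ---------------------------------------------------------------------------
# model bundle
# ---------------------------------------------------------------------------


@dataclass
class TermModel:
    """A trained per-term classifier on its selected feature columns."""

    term: str
    selected: list[int]
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    classes: list[int]  # sklearn class order; decision > 0 -> classes[1]
    final_tau: float
    ranking_values: np.ndarray
    relevance_bits: np.ndarray  # per selected feature, aligned with `selected`
    trace_steps: list[tuple[int, float, bool]]

    def decide(self, x_normalized: np.ndarray) -> int:
        x = x_normalized[self.selected]
        d2 = ((self.support_vectors - x) ** 2).sum(axis=1)
        val = float(self.dual_coef @ np.exp(-self.gamma * d2) + self.intercept)
        return self.classes[1] if val > 0 else self.classes[0]


@dataclass
class ModelBundle:
    version: int
    column_names: list[str]
    norm_stats: tuple[np.ndarray, np.ndarray]
    vocabulary_used: list[str]
    models: dict[str, TermModel]
    feature_cfg: FeatureConfig = field(default_factory=FeatureConfig)
    multiplicity_cfg: mp.ThresholdConfig = field(default_factory=mp.ThresholdConfig)


def _fit_term_model(
    fm_norm: FeatureMatrix, ann: BinaryAnnotation, res: PmeiResult
) -> TermModel:
    sel = res.trace.selected
    X = fm_norm.values[:, sel]
    clf = SVC(C=1.0, kernel="rbf", gamma=1.0 / len(sel))
    clf.fit(X, ann.labels)
    return TermModel(
        term=ann.vst_name,
        selected=[int(f) for f in sel],
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        gamma=float(clf.gamma),
        classes=[int(c) for c in clf.classes_],
        final_tau=res.trace.final_tau,
        ranking_values=res.ranking_values,
        relevance_bits=np.array([res.ranking.relevance_of(f) for f in sel]),
        trace_steps=[(s.feature, s.tau, s.accepted) for s in res.trace.steps],
    )


def train(
    images: list[LesionImage],
    ann: VSTAnnotationSet,
    feature_cfg: FeatureConfig | None = None,
    multiplicity_cfg: mp.ThresholdConfig | None = None,
    seed: int = 0,
    cv_folds: int = 5,
) -> ModelBundle:
    """Extract, normalise, select and fit one model per retained term."""
    if len(images) != len(ann.sample_ids):
        raise ValueError("number of images does not match annotation samples")
    feature_cfg = feature_cfg or FeatureConfig()
    multiplicity_cfg = multiplicity_cfg or mp.ThresholdConfig()

    fm = build_feature_matrix(
        images, ann.sample_ids, feature_cfg, multiplicity_cfg, include_multiplicity=True
    )
    fm_norm = zscore_normalize(fm)

    vocabulary = filter_vsts(ann)
    models: dict[str, TermModel] = {}
    for term in vocabulary:
        labels = ann.binary_labels(term)
        n_pos = int((labels.labels == 1).sum())
        n_neg = labels.labels.size - n_pos
        if min(n_pos, n_neg) < cv_folds:
            warnings.warn(
                f"skipping term {term!r}: minority class has "
                f"{min(n_pos, n_neg)} samples (< {cv_folds} folds)",
                stacklevel=2,
            )
            continue
        res = run_pmei(fm_norm, labels, k=cv_folds, seed=seed)
        models[term] = _fit_term_model(fm_norm, labels, res)

    return ModelBundle(
        version=BUNDLE_FORMAT_VERSION,
        column_names=list(fm.column_names),
        norm_stats=fm_norm.norm_stats,
        vocabulary_used=list(models.keys()),
        models=models,
        feature_cfg=feature_cfg,
        multiplicity_cfg=multiplicity_cfg,
    )


def predict(img: LesionImage, bundle: ModelBundle) -> dict[str, bool]:
    """Annotate one unseen image: term -> present?

    Features are extracted with the bundle's configuration and normalised
    with the stored training statistics; each per-term classifier is then
    evaluated on its selected columns.
    """
    if bundle.version != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"bundle format version {bundle.version} is not supported "
            f"(expected {BUNDLE_FORMAT_VERSION})"
        )
    if not bundle.models:
        warnings.warn("bundle contains no trained models", stacklevel=2)
        return {}
    count = mp.count_similar_lesions(img, bundle.multiplicity_cfg).count
    vec = assemble_feature_vector(img, count, bundle.feature_cfg)
    x = apply_norm_stats(vec, bundle.norm_stats)
    return {term: model.decide(x) == 1 for term, model in bundle.models.items()}


def mapping_report(bundle: ModelBundle) -> pd.DataFrame:
    """Explicit feature-to-term mapping: one row per (term, selected feature).

    Columns: vst, feature, ranking_value (0-5 scale), R_bits, tau_final.
    Rows are ordered by term, then by descending ranking value.
    """
    rows = []
    for term in bundle.vocabulary_used:
        model = bundle.models[term]
        for f, r in zip(model.selected, model.relevance_bits):
            rows.append(
                {
                    "vst": term,
                    "feature": bundle.column_names[f],
                    "ranking_value": float(model.ranking_values[f]),
                    "R_bits": float(r),
                    "tau_final": model.final_tau,
                }
            )
    df = pd.DataFrame(rows, columns=["vst", "feature", "ranking_value", "R_bits", "tau_final"])
    if len(df):
        df = df.sort_values(
            ["vst", "ranking_value"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# persistence (versioned JSON)
# ---------------------------------------------------------------------------


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    mean, sd = bundle.norm_stats
    mcfg = bundle.multiplicity_cfg
    fcfg = bundle.feature_cfg
    payload = {
        "format_version": bundle.version,
        "column_names": bundle.column_names,
        "norm_mean": mean.tolist(),
        "norm_sd": sd.tolist(),
        "vocabulary_used": bundle.vocabulary_used,
        "feature_cfg": {
            "hu_window": list(fcfg.hu_window),
            "proportion_threshold": fcfg.proportion_threshold,
        },
        "multiplicity_cfg": {
            "lambda_weight": mcfg.lambda_weight,
            "min_cluster_px": mcfg.min_cluster_px,
            "similarity_threshold": mcfg.similarity_threshold,
        },
        "models": {
            term: {
                "selected": m.selected,
                "support_vectors": m.support_vectors.tolist(),
                "dual_coef": m.dual_coef.tolist(),
                "intercept": m.intercept,
                "gamma": m.gamma,
                "classes": m.classes,
                "final_tau": m.final_tau,
                "ranking_values": m.ranking_values.tolist(),
                "relevance_bits": m.relevance_bits.tolist(),
                "trace_steps": [[f, t, bool(a)] for f, t, a in m.trace_steps],
            }
            for term, m in bundle.models.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_bundle(path: str | Path) -> ModelBundle:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"refusing to load bundle with format version {version!r} "
            f"(expected {BUNDLE_FORMAT_VERSION})"
        )
    models = {
        term: TermModel(
            term=term,
            selected=[int(f) for f in d["selected"]],
            support_vectors=np.asarray(d["support_vectors"], float),
            dual_coef=np.asarray(d["dual_coef"], float),
            intercept=float(d["intercept"]),
            gamma=float(d["gamma"]),
            classes=[int(c) for c in d["classes"]],
            final_tau=float(d["final_tau"]),
            ranking_values=np.asarray(d["ranking_values"], float),
            relevance_bits=np.asarray(d["relevance_bits"], float),
            trace_steps=[(int(f), float(t), bool(a)) for f, t, a in d["trace_steps"]],
        )
        for term, d in payload["models"].items()
    }
    fcfg = FeatureConfig(
        hu_window=tuple(payload["feature_cfg"]["hu_window"]),
        proportion_threshold=payload["feature_cfg"]["proportion_threshold"],
    )
    mcfg_d = payload["multiplicity_cfg"]
    mcfg = mp.ThresholdConfig(
        lambda_weight=mcfg_d["lambda_weight"],
        min_cluster_px=int(mcfg_d["min_cluster_px"]),
        similarity_threshold=float(mcfg_d["similarity_threshold"]),
    )
    return ModelBundle(
        version=int(version),
        column_names=list(payload["column_names"]),
        norm_stats=(
            np.asarray(payload["norm_mean"], float),
            np.asarray(payload["norm_sd"], float),
        ),
        vocabulary_used=list(payload["vocabulary_used"]),
        models=models,
        feature_cfg=fcfg,
        multiplicity_cfg=mcfg,
    )
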