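"""End-to-end BGCMF prediction.

Stages: GIP kernels on the raw binary associations -> fusion with the
precomputed miRNA/disease similarities -> optional WKNKN imputation -> the
bipartite-graph score Y1 and the CMF score Y2, both computed from the
imputed matrix -> the final score w * Y1 + (1 - w) * Y2.

GIP kernels are deliberately computed on the raw binary matrix (interaction
profiles are defined on known associations), while both predictors consume
the WKNKN-processed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .bipartite import bipartite_scores
from .cmf import CmfParams, fit_cmf
from .data_io import AssociationMatrix, PredictionMatrix, RankedList, SimilarityMatrix, rank_candidates
from .errors import LabelError, ParameterError, PipelineStageError
from .similarity import FusionParams, GipParams, gip_kernel, integrate_similarity
from .wknkn import WknknParams, wknkn_impute

__all__ = ["PipelineConfig", "bgcmf_predict", "predict_single"]


@dataclass(frozen=True)
class PipelineConfig:
    fusion: FusionParams = field(default_factory=FusionParams)
    gip: GipParams = field(default_factory=GipParams)
    wknkn: WknknParams = field(default_factory=WknknParams)
    wknkn_enabled: bool = True
    cmf: CmfParams = field(default_factory=CmfParams)
    combine_weight: float = 0.5

    def __post_init__(self):
        if not 0 <= self.combine_weight <= 1:
            raise ParameterError(f"combine_weight must be in [0, 1], got {self.combine_weight}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from a flat key-value mapping (see ``to_dict`` for keys)."""
        d = dict(d)
        return cls(
            fusion=FusionParams(alpha=d.pop("alpha", 0.5)),
            gip=GipParams(
                gamma_prime=d.pop("gamma_prime", 1.0),
                normalize=d.pop("gip_normalize", True),
            ),
            wknkn=WknknParams(K=d.pop("wknkn_k", 7), p=d.pop("wknkn_p", 0.6)),
            wknkn_enabled=d.pop("wknkn_enabled", True),
            cmf=CmfParams(
                lambda_l=d.pop("lambda_l", 1.0),
                lambda_d=d.pop("lambda_d", 0.25),
                lambda_t=d.pop("lambda_t", 0.25),
                k=d.pop("cmf_k", 50),
                max_iter=d.pop("cmf_max_iter", 100),
                tol=d.pop("cmf_tol", 1e-6),
                seed=d.pop("seed", 0),
            ),
            combine_weight=d.pop("combine_weight", 0.5),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "alpha": self.fusion.alpha,
            "gamma_prime": self.gip.gamma_prime,
            "gip_normalize": self.gip.normalize,
            "wknkn_k": self.wknkn.K,
            "wknkn_p": self.wknkn.p,
            "wknkn_enabled": self.wknkn_enabled,
            "lambda_l": self.cmf.lambda_l,
            "lambda_d": self.cmf.lambda_d,
            "lambda_t": self.cmf.lambda_t,
            "cmf_k": self.cmf.k,
            "cmf_max_iter": self.cmf.max_iter,
            "cmf_tol": self.cmf.tol,
            "combine_weight": self.combine_weight,
            "seed": self.cmf.seed,
        }


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def bgcmf_predict(
    Y: AssociationMatrix,
    Sm: SimilarityMatrix,
    Sd: SimilarityMatrix,
    config: PipelineConfig = PipelineConfig(),
) -> PredictionMatrix:
    """Run the full prediction pipeline and return the fused score matrix.

    The CMF latent dimension is clipped to min(n, m) so one configuration
    serves problems of any size.
    """
    if Sm.labels != Y.row_labels:
        raise LabelError("miRNA similarity labels must equal Y row labels")
    if Sd.labels != Y.col_labels:
        raise LabelError("disease similarity labels must equal Y column labels")

    with _stage("gip"):
        Gm = gip_kernel(Y, "miRNA", config.gip)
        Gd = gip_kernel(Y, "disease", config.gip)
    with _stage("fusion"):
        Km = integrate_similarity(Sm, Gm, config.fusion)
        Kd = integrate_similarity(Sd, Gd, config.fusion)
    with _stage("wknkn"):
        if config.wknkn_enabled:
            Y_work = wknkn_impute(Y, Km, Kd, config.wknkn)
        else:
            Y_work = Y.values.astype(float)
    with _stage("bipartite"):
        Y1 = bipartite_scores(Km, Kd, Y_work)
    with _stage("cmf"):
        k_eff = min(config.cmf.k, Y.n, Y.m)
        cmf_params = replace(config.cmf, k=k_eff)
        _, Y2, _ = fit_cmf(Y_work, Km.values, Kd.values, cmf_params)
    w = config.combine_weight
    scores = w * Y1 + (1.0 - w) * Y2
    return PredictionMatrix(
        scores,
        Y.row_labels,
        Y.col_labels,
        provenance=("gip", "fusion") + (("wknkn",) if config.wknkn_enabled else ()) + ("bipartite", "cmf", "combine"),
    )


def predict_single(
    Y: AssociationMatrix,
    Sm: SimilarityMatrix,
    Sd: SimilarityMatrix,
    config: PipelineConfig,
    disease: str,
    top_n: int,
) -> RankedList:
    """Predict and rank the top candidate miRNAs for one disease."""
    scores = bgcmf_predict(Y, Sm, Sd, config)
    return rank_candidates(Y, scores, disease, top_n)
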