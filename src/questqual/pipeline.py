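"""The end-to-end quality model: featurize, cluster, label, report.

statsmodels-style surface: :class:`QuestionQualityModel` is built from
a corpus (DataFrame or file), ``fit()`` runs feature extraction and
k-means tiering and returns a :class:`QuestionQualityResults` carrying
the feature table, the fitted cluster model, per-question tier
assignments, the advisory elbow diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cli_io
from .metrics import FEATURE_COLUMNS, featurize_corpus
from .quality_cluster import (
    ClusterModel,
    fit_kmeans,
    label_clusters,
    select_k_elbow,
    stratified_sample,
)
from .textlex import LexiconSet, default_lexicon_set, load_lexicon_set

__all__ = ["QuestionQualityModel", "QuestionQualityResults"]

logger = logging.getLogger(__name__)

QUALITY_NAMES = {1: "high", 2: "average", 3: "low"}


class QuestionQualityModel:
    """Quality-measurement model over a corpus of posted questions."""

    def __init__(
        self,
        corpus: pd.DataFrame,
        lexicons: LexiconSet | None = None,
        k: int = 3,
        body_only: bool = False,
    ):
        self.corpus = cli_io._validate_corpus(corpus)
        self.lexicons = lexicons if lexicons is not None else default_lexicon_set()
        self.k = k
        self.body_only = body_only

    @classmethod
    def from_csv(cls, path, lexicon_dir=None, **kwargs) -> "QuestionQualityModel":
        lex = load_lexicon_set(lexicon_dir) if lexicon_dir else None
        return cls(cli_io.read_corpus(path), lexicons=lex, **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "QuestionQualityModel":
        return cls(frame, **kwargs)

    def fit(
        self,
        seed: int = 0,
        n_restarts: int = 20,
        k_range: tuple[int, int] | None = (1, 8),
    ) -> "QuestionQualityResults":
        """Featurize the corpus, fit k-means in standardized
        (readability, clarity) space, rank clusters into quality tiers.

        Records with missing readability (empty text) are excluded
        from clustering and reported; ``k_range`` controls the
        advisory elbow scan (None disables it).
        """
        features = featurize_corpus(
            self.corpus, lexicons=self.lexicons, body_only=self.body_only
        )
        usable = features[np.isfinite(features["readability"])]
        excluded = features.loc[
            ~np.isfinite(features["readability"]), "id"
        ].tolist()
        if excluded:
            logger.warning(
                "%d record(s) excluded from clustering (empty text): %s",
                len(excluded), excluded[:10],
            )
        points = usable[["readability", "clarity"]].to_numpy()

        model = fit_kmeans(points, self.k, seed=seed, n_restarts=n_restarts)
        elbow_k = None
        if k_range is not None:
            lo, hi = k_range
            hi = min(hi, len(points))
            if hi - lo >= 2:
                elbow_k, curve = select_k_elbow(
                    points, range(lo, hi + 1), seed=seed, n_restarts=max(n_restarts // 2, 5)
                )
                model.sse_curve = curve
                if elbow_k != self.k:
                    logger.info(
                        "elbow criterion suggests k=%d (pipeline uses k=%d)",
                        elbow_k, self.k,
                    )
        if self.k == 3:
            label_clusters(model, points)
            quality = model.quality_of(points)
        else:
            quality = np.full(len(points), -1)

        assignments = pd.DataFrame(
            {
                "id": usable["id"].to_numpy(),
                "cluster": model.assign(points),
                "quality": quality,
            }
        )
        return QuestionQualityResults(
            model=self,
            features=features,
            cluster_model=model,
            assignments=assignments,
            elbow_k=elbow_k,
            excluded_ids=excluded,
            seed=seed,
        )


class QuestionQualityResults:
    """Fitted quality measurement: features, tiers, diagnostics."""

    def __init__(
        self, model, features, cluster_model: ClusterModel,
        assignments: pd.DataFrame, elbow_k, excluded_ids, seed: int,
    ):
        self.model = model
        self.features = features
        self.cluster_model = cluster_model
        self.assignments = assignments
        self.elbow_k = elbow_k
        self.excluded_ids = excluded_ids
        self.seed = seed

    @property
    def quality(self) -> pd.Series:
        """Quality level (1 high / 2 average / 3 low) per record id."""
        return self.assignments.set_index("id")["quality"]

    def tier_table(self) -> pd.DataFrame:
        """Per-tier count and indicator ranges (the cluster profile)."""
        merged = self.assignments.merge(self.features, on="id")
        rows = []
        for q, grp in merged.groupby("quality", sort=True):
            rows.append(
                {
                    "quality": q,
                    "label": QUALITY_NAMES.get(q, str(q)),
                    "n": len(grp),
                    "readability_mean": grp["readability"].mean(),
                    "readability_min": grp["readability"].min(),
                    "readability_max": grp["readability"].max(),
                    "clarity_mean": grp["clarity"].mean(),
                    "clarity_min": grp["clarity"].min(),
                    "clarity_max": grp["clarity"].max(),
                }
            )
        return pd.DataFrame(rows)

    def validation_sample(self, fraction: float = 0.10, seed: int | None = None):
        """Stratified 10% (default) sample of ids for human judging."""
        return stratified_sample(
            self.assignments, fraction=fraction,
            seed=self.seed if seed is None else seed,
        )

    def summary(self) -> str:
        t = self.tier_table()
        lines = [
            "Question quality measurement",
            f"  n = {len(self.features)} records "
            f"({len(self.excluded_ids)} excluded, empty text)",
            f"  k = {self.cluster_model.k} (seed {self.seed}, "
            f"{self.cluster_model.n_restarts} restarts, "
            f"SSE {self.cluster_model.sse:.3f})"
            + (f"; elbow suggests k = {self.elbow_k}" if self.elbow_k else ""),
            "",
            f"  {'tier':<10}{'n':>6}{'readability (min..max)':>28}"
            f"{'clarity (min..max)':>26}",
        ]
        for row in t.itertuples(index=False):
            lines.append(
                f"  {row.label:<10}{row.n:>6}"
                f"{row.readability_mean:>10.2f} ({row.readability_min:.2f}.."
                f"{row.readability_max:.2f})"
                f"{row.clarity_mean:>10.2f} ({row.clarity_min:.2f}.."
                f"{row.clarity_max:.2f})"
            )
        return "\n".join(lines)

    def save(self, out_dir) -> dict[str, str]:
        """Write features.csv, assignments.csv and model.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "features": str(out / "features.csv"),
            "assignments": str(out / "assignments.csv"),
            "model": str(out / "model.json"),
        }
        self.features.to_csv(paths["features"], index=False)
        self.assignments.to_csv(paths["assignments"], index=False)
        Path(paths["model"]).write_text(self.cluster_model.to_json())
        return paths


def run_pipeline(config: cli_io.PipelineConfig) -> dict:
    """Execute the configured stages end to end, saving artifacts.

    Stages: read corpus -> featurize -> cluster/label -> validation
    sample -> (optional) judge statistics -> (optional) determinant
    regression. Returns the artifact paths and in-memory results; any
    stage failure aborts with the stage name while earlier outputs
    remain on disk.
    """
    from .determinants import QualityDeterminantsModel, group_tests
    from .validation import JudgeRatings, panel_kappa, rating_cluster_correlation

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read_corpus"
    try:
        model = QuestionQualityModel.from_csv(
            config.corpus_path, lexicon_dir=config.lexicon_dir,
            k=config.k, body_only=config.body_only,
        )
        stage = "featurize/cluster"
        results = model.fit(
            seed=config.seed, n_restarts=config.n_restarts, k_range=config.k_range
        )
        artifacts = results.save(out)
        report: dict = {"tiers": results.tier_table().to_dict(orient="records")}

        stage = "validation_sample"
        sample = results.validation_sample(fraction=config.sample_fraction)
        (out / "validation_sample.txt").write_text("\n".join(map(str, sample)) + "\n")
        report["validation_sample_size"] = len(sample)

        if config.ratings_path:
            stage = "judge_statistics"
            ratings = JudgeRatings.from_long(cli_io.read_ratings(config.ratings_path))
            kappas = panel_kappa(ratings)
            report["kappa"] = {
                "pairs": {f"{a}|{b}": v for (a, b), v in kappas["pairs"].items()},
                "mean": kappas["mean"],
            }
            common = ratings.table.index.intersection(results.quality.index)
            if len(common) >= 3:
                from .validation import consensus_by_majority

                consensus = consensus_by_majority(
                    JudgeRatings(ratings.table.loc[common]), on_tie="drop"
                )
                report["pearson_r"] = rating_cluster_correlation(
                    consensus.to_numpy(),
                    results.quality.loc[consensus.index].to_numpy(),
                )

        if config.codes_path:
            stage = "determinants"
            codes = cli_io.read_codes(config.codes_path)
            merged = (
                results.assignments[["id", "quality"]]
                .merge(codes, on="id")
                .merge(results.features[["id", "word_count", "words_per_sentence"]], on="id")
            )
            det = QualityDeterminantsModel.from_dataframe(
                merged.drop(columns=["id"]), quality_col="quality"
            ).fit(ridge=config.ridge)
            det.params.to_csv(out / "coefficients.csv", index=False)
            (out / "regression_summary.txt").write_text(det.summary() + "\n")
            report["regression"] = {
                "llf": det.llf,
                "converged": det.converged,
                "separation_terms": list(det.separation_terms),
            }
            if "platform" in model.corpus.columns:
                plat = model.corpus[["id", "platform"]].merge(
                    results.features, on="id"
                ).merge(codes, on="id")
                gt = group_tests(plat.drop(columns=["id"]), group_col="platform")
                gt.to_csv(out / "group_tests.csv", index=False)

        stage = "manifest"
        import json

        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        cli_io.write_manifest(
            out / "manifest.json", config,
            counts={"records": len(model.corpus), "excluded": len(results.excluded_ids)},
        )
        return {"artifacts": artifacts, "report": report, "results": results}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
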