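"""The acceptability reference framework: map + clusters + zones.

The framework is fit once on a large reference corpus of evaluations
(the study pooled 2,611 evaluations from seven countries) and then kept
fixed: medicines under investigation are projected as supplementary
individuals that have no influence on the model, so their scores are
comparable across studies.

Fitting chain: impute missing cells (regularized iterative MCA) -> MCA of
the (fuzzy) indicator table, three dimensions retained -> HCPC (Ward +
k-means consolidation, k = 2) on the map coordinates -> v-test
characterization of the clusters -> green/red zone labelling.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cluster import (
    ClusterPartition,
    assign_zone,
    enrichment_table,
    hcpc,
    label_profiles,
)
from .codebook import DEFAULT_CODEBOOK, Codebook
from .impute import impute
from .mca import MCA, build_indicator
from .schema import EvaluationSet
from .scoring import AcceptabilityScore, score_set

__all__ = ["ReferenceFramework"]


class ReferenceFramework(BaseEstimator):
    """Fit, persist and apply the acceptability reference framework.

    Parameters
    ----------
    n_components : int, default 3
        Map dimensions retained (the 3D acceptability map).
    n_clusters : int, default 2
        Acceptability profiles; the published framework uses two.
    impute_tol, impute_max_iter : imputation stopping rule.

    Attributes (after ``fit``)
    --------------------------
    mca_ : fitted :class:`acceptmap.mca.MCA`
    partition_ : labelled :class:`acceptmap.cluster.ClusterPartition`
    enrichment_ : DataFrame of per-cluster v-tests
    coordinates_ : (N, 3) active individual coordinates
    """

    def __init__(
        self,
        n_components: int = 3,
        n_clusters: int = 2,
        impute_tol: float = 1e-6,
        impute_max_iter: int = 1000,
    ):
        self.n_components = n_components
        self.n_clusters = n_clusters
        self.impute_tol = impute_tol
        self.impute_max_iter = impute_max_iter

    # -- fitting ---------------------------------------------------------
    def fit(self, evalset: EvaluationSet, y=None) -> "ReferenceFramework":
        self.codebook_ = evalset.codebook
        if evalset.n_missing_cells:
            result = impute(
                evalset,
                n_components=self.n_components,
                tol=self.impute_tol,
                max_iter=self.impute_max_iter,
            )
            fuzzy = result.fuzzy_indicator
            hard = build_indicator(result.hard_calls)
        else:
            fuzzy = build_indicator(evalset)
            hard = fuzzy
        self.mca_ = MCA(n_components=self.n_components).fit(fuzzy)
        self.coordinates_ = self.mca_.row_coordinates_
        partition = hcpc(self.coordinates_, k=self.n_clusters)
        hard_kept = hard.loc[:, self.mca_.columns_] if self.mca_.dropped_columns_ else hard
        if self.n_clusters == 2:
            partition = label_profiles(partition, hard_kept, self.codebook_)
        self.partition_ = partition
        self.enrichment_ = enrichment_table(partition, hard_kept)
        return self

    # -- application -----------------------------------------------------
    def project(self, data) -> np.ndarray:
        """Supplementary projection of evaluations or (fuzzy) indicator rows."""
        if isinstance(data, EvaluationSet):
            data = build_indicator(data)
        return self.mca_.transform(data)

    def assign_zone(self, points: np.ndarray) -> np.ndarray:
        return assign_zone(points, self.partition_)

    def score(
        self,
        evalset: EvaluationSet,
        where=None,
        level: float = 0.90,
        boundary_points: int = 360,
        label: str = "",
    ) -> AcceptabilityScore:
        return score_set(
            evalset,
            self,
            where=where,
            level=level,
            boundary_points=boundary_points,
            label=label,
        )

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        self._check_fitted()
        payload = {
            "format": "acceptmap-framework-v1",
            "codebook_hash": self.codebook_.hash(),
            "n_components": self.n_components,
            "n_clusters": self.n_clusters,
            "mca": self.mca_.to_dict(),
            "partition": {
                "centroids": self.partition_.centroids.tolist(),
                "dendrogram_heights": self.partition_.dendrogram_heights.tolist(),
                "cluster_sizes": np.bincount(
                    self.partition_.labels, minlength=self.n_clusters
                ).tolist(),
                "profile_names": {
                    str(k): v for k, v in self.partition_.profile_names.items()
                },
                "zone_names": {str(k): v for k, v in self.partition_.zone_names.items()},
            },
            "enrichment": self.enrichment_.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(
        cls, path: str | Path, codebook: Codebook | None = None
    ) -> "ReferenceFramework":
        codebook = codebook or DEFAULT_CODEBOOK
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "acceptmap-framework-v1":
            raise ValueError(f"{path} is not a serialized reference framework")
        if payload["codebook_hash"] != codebook.hash():
            raise ValueError(
                "codebook mismatch: the framework was fitted under a different codebook"
            )
        fw = cls(
            n_components=payload["n_components"], n_clusters=payload["n_clusters"]
        )
        fw.codebook_ = codebook
        fw.mca_ = MCA.from_dict(payload["mca"])
        part = payload["partition"]
        fw.partition_ = ClusterPartition(
            labels=np.array([], dtype=int),  # member labels are not persisted
            centroids=np.asarray(part["centroids"]),
            dendrogram_heights=np.asarray(part["dendrogram_heights"]),
            profile_names={int(k): v for k, v in part["profile_names"].items()},
            zone_names={int(k): v for k, v in part["zone_names"].items()},
        )
        fw.enrichment_ = pd.DataFrame(payload["enrichment"])
        fw.coordinates_ = None
        return fw

    def _check_fitted(self) -> None:
        if not hasattr(self, "mca_"):
            raise RuntimeError("ReferenceFramework is not fitted")
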