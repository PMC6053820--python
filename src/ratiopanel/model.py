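"""Model/Results interface tying the discovery stages together.

:class:`RatioPanelModel` holds one contrast's feature data (per-sample
dCT values of every eligible ncRNA pair) and binary labels; ``fit()``
runs the screen -> ROC -> SVM-RFE -> panel/CV cascade and returns a
:class:`RatioPanelResults` carrying the per-pair statistics table, the
fitted panel, its cross-validated performance, and evaluation helpers
for independent cohorts.

Typical use::

    model = RatioPanelModel.from_matrices(ct, metadata, contrast="LAC vs. Control",
                                          counts=counts, annotations=ann)
    res = model.fit(seed=7)
    print(res.summary())
    val = res.evaluate(ct_validation, metadata_validation)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import roc as _roc
from . import screen as _screen
from . import svmpanel as _svm
from .exceptions import EmptyGroupError, ParameterError
from .io import CountMatrix, CtMatrix, align_samples
from .metrics import ConfusionMetrics, evaluate_panel
from .ratios import (
    DEFAULT_EXCLUDE_CLASSES,
    DEFAULT_MIN_COPIES,
    enumerate_pairs,
    filter_by_abundance,
    pair_features,
)


@dataclass(frozen=True)
class Contrast:
    """A two-arm comparison; the positive arm is the disease-like one."""

    name: str
    positive: tuple[str, ...]
    negative: tuple[str, ...]


CONTRASTS = {
    "LAC+Benign vs. Control": Contrast(
        "LAC+Benign vs. Control", ("LAC", "BENIGN"), ("CONTROL",)
    ),
    "LAC vs. Control": Contrast("LAC vs. Control", ("LAC",), ("CONTROL",)),
    "LAC vs. Benign": Contrast("LAC vs. Benign", ("LAC",), ("BENIGN",)),
}


def resolve_contrast(contrast) -> Contrast:
    if isinstance(contrast, Contrast):
        return contrast
    try:
        return CONTRASTS[contrast]
    except KeyError:
        raise ParameterError(
            f"unknown contrast {contrast!r}; known: {list(CONTRASTS)}"
        ) from None


class RatioPanelModel:
    """Ratio-pair biomarker discovery model for one contrast.

    Parameters
    ----------
    features : DataFrame, samples x pairs
        Per-sample dCT (log2 ratio) values; column names are ``a/b``
        pair ids.
    labels : array-like of bool
        True for the contrast's positive (disease-like) arm.
    contrast : Contrast or str
        Which comparison the labels encode (used for reporting only).
    """

    def __init__(self, features: pd.DataFrame, labels, contrast="LAC vs. Control"):
        self.features = features
        self.labels = np.asarray(labels).astype(bool)
        if self.labels.shape[0] != features.shape[0]:
            raise ParameterError("labels length must match feature rows")
        if self.labels.all() or not self.labels.any():
            raise EmptyGroupError("contrast needs samples in both arms")
        self.contrast = resolve_contrast(contrast)

    # -- construction -------------------------------------------------
    @classmethod
    def from_matrices(
        cls,
        ct: CtMatrix,
        metadata: pd.DataFrame,
        contrast="LAC vs. Control",
        annotations: pd.DataFrame | None = None,
        counts: CountMatrix | None = None,
        min_copies: int = DEFAULT_MIN_COPIES,
        exclude_classes=DEFAULT_EXCLUDE_CLASSES,
    ) -> "RatioPanelModel":
        """Assemble the pair-feature matrix from a CT matrix and metadata.

        When a sequencing count matrix is supplied, the copy-number filter
        restricts the species universe first (a species needs
        ``min_copies`` reads in at least one pooled sample); annotations
        then drop excluded classes (pre-miRNAs) from pair enumeration.
        """
        contrast = resolve_contrast(contrast)
        species = list(ct.species_ids)
        if counts is not None:
            kept = set(filter_by_abundance(counts, min_copies).species_ids)
            species = [s for s in species if s in kept]
        if annotations is not None:
            pairs = enumerate_pairs(annotations, species, exclude_classes)
        else:
            from itertools import combinations

            pairs = list(combinations(species, 2))
        meta = align_samples(ct.sample_ids, metadata)
        arm = meta["group"].isin(contrast.positive + contrast.negative).to_numpy()
        sub = CtMatrix(ct.ct.loc[species, np.asarray(ct.sample_ids)[arm]],
                       replicate_count=ct.replicate_count)
        feats = pair_features(sub, pairs)
        labels = meta.loc[arm, "group"].isin(contrast.positive).to_numpy()
        return cls(feats, labels, contrast)

    # -- fitting ------------------------------------------------------
    def fit(
        self,
        fc_min: float = 2.0,
        q_max: float = 0.05,
        sen_min: float = 0.80,
        spe_min: float = 0.80,
        auc_min: float = 0.800,
        correction: str = "benjamini_hochberg",
        t_variant: str = "student",
        panel_size: int | str = "auto",
        max_panel_size: int = 10,
        max_rfe_features: int = 50,
        k: int = 10,
        C: float = _svm.DEFAULT_C,
        seed: int = 0,
    ) -> "RatioPanelResults":
        """Run the full discovery cascade and return the results object.

        Stages: per-pair Student's t screen with multiplicity correction
        and fold-change filter; per-candidate ROC with Youden operating
        points and the strict SEN/SPE/AUC marker criteria; SVM-RFE ranking
        of the markers (falling back to candidates when no pair meets all
        three ROC criteria; capped at ``max_rfe_features`` by AUC);
        rank-prefix panel assembly with stratified ``k``-fold CV.
        """
        pos = self.labels
        neg = ~self.labels
        stats = _screen.screen_pairs(
            self.features, pos, neg, variant=t_variant, correction=correction
        )
        candidates = _screen.select_candidates(stats, fc_min=fc_min, q_max=q_max)
        candidates = _roc.add_roc_stats(candidates, self.features, pos, neg)
        markers = _roc.select_markers(
            candidates, sen_min=sen_min, spe_min=spe_min, auc_min=auc_min
        )
        rfe_pool = markers if len(markers) else candidates
        rfe_pool = rfe_pool.sort_values(
            ["auc", "pair_id"], ascending=[False, True]
        ).head(max_rfe_features)

        panel = None
        ranked: list[str] = []
        if len(rfe_pool):
            feats = self._oriented_features(rfe_pool)
            ranked = _svm.svm_rfe_rank(feats, self.labels, C=C)
            panel = _svm.build_panel(
                ranked,
                feats,
                self.labels,
                size=panel_size,
                k=k,
                seed=seed,
                C=C,
                max_size=max_panel_size,
            )
        return RatioPanelResults(
            model=self,
            pair_stats=stats,
            candidates=candidates,
            markers=markers,
            ranking=ranked,
            panel=panel,
            params={
                "fc_min": fc_min, "q_max": q_max, "sen_min": sen_min,
                "spe_min": spe_min, "auc_min": auc_min,
                "correction": correction, "t_variant": t_variant,
                "panel_size": panel_size, "max_panel_size": max_panel_size,
                "max_rfe_features": max_rfe_features, "k": k, "C": C,
                "seed": seed,
            },
        )

    def _oriented_features(self, table: pd.DataFrame) -> pd.DataFrame:
        """Oriented (disease-positive) feature columns for table rows."""
        cols = {}
        for _, row in table.iterrows():
            raw = self.features[row["feature_id"]]
            cols[row["pair_id"]] = -raw if row["pair_id"] != row["feature_id"] else raw
        return pd.DataFrame(cols, index=self.features.index)


@dataclass
class RatioPanelResults:
    """Fit output: per-pair statistics, selected panel, CV performance."""

    model: RatioPanelModel
    pair_stats: pd.DataFrame
    candidates: pd.DataFrame
    markers: pd.DataFrame
    ranking: list[str]
    panel: _svm.Panel | None
    params: dict = field(default_factory=dict)

    @property
    def cv_metrics(self) -> ConfusionMetrics | None:
        return None if self.panel is None else self.panel.cv_metrics

    # -- application to cohorts ---------------------------------------
    def decision_values(self, ct: CtMatrix, metadata: pd.DataFrame):
        """Panel decision values on an independent cohort (no refitting)."""
        if self.panel is None:
            raise ParameterError("no panel was fitted (no candidate pairs)")
        contrast = self.model.contrast
        meta = align_samples(ct.sample_ids, metadata)
        arm = meta["group"].isin(contrast.positive + contrast.negative).to_numpy()
        samples = np.asarray(ct.sample_ids)[arm]
        pairs = [tuple(p.split("/", 1)) for p in self.panel.pair_ids]
        feats = pair_features(
            CtMatrix(ct.ct.loc[:, samples], replicate_count=ct.replicate_count), pairs
        )
        labels = meta.loc[arm, "group"].isin(contrast.positive).to_numpy()
        return _svm.apply_panel(self.panel, feats), labels

    def evaluate(self, ct: CtMatrix, metadata: pd.DataFrame) -> ConfusionMetrics:
        """Confusion metrics of the fitted panel on an independent cohort.

        The training-stage decision threshold is carried over unchanged.
        """
        dec, labels = self.decision_values(ct, metadata)
        return evaluate_panel(dec.to_numpy(), labels, self.panel.threshold)

    # -- presentation -------------------------------------------------
    def summary(self, max_rows: int = 10) -> str:
        c = self.model.contrast
        n_pos = int(self.model.labels.sum())
        n_neg = int((~self.model.labels).sum())
        lines = [
            "Ratio-pair panel discovery",
            "==========================",
            f"Contrast:          {c.name}  ({n_pos} vs. {n_neg} samples)",
            f"Pairs screened:    {len(self.pair_stats)}",
            f"Candidates (FC>={self.params.get('fc_min', 2.0)}, "
            f"q<={self.params.get('q_max', 0.05)}): {len(self.candidates)}",
            f"ROC markers:       {len(self.markers)}",
        ]
        if self.panel is not None:
            m = self.panel.cv_metrics
            lines += [
                f"Panel size:        {self.panel.size}",
                f"CV AUC:            {m.auc:.3f}",
                f"CV SEN/SPE:        {m.sen:.3f} / {m.spe:.3f}",
                "",
                "Panel pairs (rank order):",
            ]
            stats = self.candidates.set_index("pair_id")
            for pid in self.panel.pair_ids:
                if pid in stats.index:
                    row = stats.loc[pid]
                    lines.append(
                        f"  {pid:40s} RATIO {row['ratio']:.2f}  FC {row['fold_change']:.2f}"
                        f"  AUC {row['auc']:.3f}"
                    )
                else:
                    lines.append(f"  {pid}")
        else:
            lines.append("Panel:             none (no candidate pairs)")
        return "\n".join(lines)

    def plot_roc(self, ax=None, label: str | None = None):
        """ROC curve of the panel's pooled cross-validation decision values."""
        import matplotlib.pyplot as plt

        if self.panel is None or self.panel.cv_decision is None:
            raise ParameterError("no fitted panel to plot")
        curve = _roc.roc_curve(self.panel.cv_decision.to_numpy(), self.model.labels)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve.fpr, curve.tpr,
                label=label or f"{self.model.contrast.name} (AUC {curve.auc:.3f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax
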