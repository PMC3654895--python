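"""ROC/AUC evaluation and the two validation protocols.

Two experiment designs are supported:

* per-allele k-fold cross-validation (allele-specific by default, with a
  pan mode that adds every other allele's records to each training fold),
  mirroring benchmark comparisons against allele-specific predictors; and
* leave-one-allele-out: all records of one allele are held out and the
  model trains on the remaining alleles only, simulating prediction for
  an allele with no binding data.  Supertype labels annotate the report.

AUC is the Mann-Whitney pair statistic (ties 0.5), i.e. the probability
that a random binder outscores a random non-binder; records are labelled
binders below 500 nM by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .encoding import AlleleSequence

logger = logging.getLogger(__name__)

BINDER_THRESHOLD_NM = 500.0


def label_binder(ic50_nM: float,
                 threshold_nM: float = BINDER_THRESHOLD_NM) -> bool:
    """True iff IC50 is strictly below the binder threshold."""
    if ic50_nM <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return ic50_nM < threshold_nM


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; requires both classes present."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores, labels) -> list[tuple[float, float]]:
    """(false positive rate, true positive rate) points of the ROC curve."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(np.asarray(labels, dtype=bool),
                            np.asarray(scores, dtype=float))
    return list(zip(map(float, fpr), map(float, tpr)))


# ---------------------------------------------------------------------------
# supertypes

class SupertypeMap(dict):
    """allele name -> supertype label (e.g. A*0201 -> A2)."""

    @classmethod
    def from_tsv(cls, path) -> "SupertypeMap":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(zip(df["allele"], df["supertype"]))

    @classmethod
    def load_default(cls) -> "SupertypeMap":
        """Bundled map covering the classical A1/A2/A3/A24/A26 and
        B7/B8/B27/B39/B44/B58/B62 supertype assignments."""
        with resources.as_file(
                resources.files("annbm.data") / "supertypes.tsv") as p:
            return cls.from_tsv(p)

    def to_tsv(self, path) -> None:
        pd.DataFrame(sorted(self.items()),
                     columns=["allele", "supertype"]
                     ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reports

@dataclass
class AlleleResult:
    allele: str
    n_peptides: int
    auc: float
    roc: list[tuple[float, float]] = field(default_factory=list)
    supertype: str = ""


@dataclass
class EvalReport:
    mode: str
    results: list[AlleleResult] = field(default_factory=list)
    seed: int = 0

    @property
    def macro_average_auc(self) -> float:
        """Unweighted mean AUC over evaluated alleles."""
        if not self.results:
            raise ValueError("empty report")
        return float(np.mean([r.auc for r in self.results]))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"allele": r.allele, "supertype": r.supertype,
                 "AUC": r.auc, "n_peptides": r.n_peptides}
                for r in self.results]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        avg = pd.DataFrame([{"allele": "AVG", "supertype": "",
                             "AUC": self.macro_average_auc,
                             "n_peptides": df["n_peptides"].sum()}])
        with open(path, "w") as fh:
            fh.write(f"# annbm evaluate mode={self.mode} seed={self.seed}\n")
            pd.concat([df, avg]).to_csv(fh, sep="\t", index=False,
                                        float_format="%.4f")

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "macro_average_auc": self.macro_average_auc,
            "alleles": [{"allele": r.allele, "supertype": r.supertype,
                         "n_peptides": r.n_peptides, "auc": r.auc,
                         "roc": r.roc} for r in self.results],
        }


def _subseed(seed: int, k: int) -> int:
    return (seed * 100003 + 7919 * k + 1) % (2 ** 31)


# ---------------------------------------------------------------------------
# protocols

def evaluate_per_allele(df: pd.DataFrame, alleles: dict[str, AlleleSequence],
                        model_factory, k_folds: int = 5, seed: int = 0,
                        mode: str = "allele_specific",
                        supertypes: SupertypeMap | None = None) -> EvalReport:
    """Per-allele k-fold cross-validation.

    ``model_factory(seed)`` must return an object with
    ``fit(df, alleles)`` and ``predict_affinity(df, alleles)``.  In
    ``"pan"`` mode every training fold additionally includes all records
    of the other alleles.  Alleles with fewer than ``k_folds`` records or
    a single class are skipped with a warning.
    """
    from sklearn.model_selection import KFold

    if mode not in ("allele_specific", "pan"):
        raise ValueError(f"unknown mode {mode!r}")
    report = EvalReport(mode=f"cv-{mode}", seed=seed)
    for k, allele in enumerate(sorted(df["allele"].unique())):
        sub = df[df["allele"] == allele].reset_index(drop=True)
        if len(sub) < k_folds:
            logger.warning("allele %s has %d < %d records; skipped",
                           allele, len(sub), k_folds)
            continue
        labels = sub["binder"].to_numpy()
        if labels.all() or not labels.any():
            logger.warning("allele %s has a single class; skipped", allele)
            continue
        others = df[df["allele"] != allele]
        preds = np.empty(len(sub))
        splitter = KFold(n_splits=k_folds, shuffle=True,
                         random_state=_subseed(seed, k))
        for f, (tr, te) in enumerate(splitter.split(sub)):
            train_df = sub.iloc[tr]
            if mode == "pan":
                train_df = pd.concat([train_df, others], ignore_index=True)
            model = model_factory(_subseed(seed, 1000 * k + f))
            model.fit(train_df, alleles)
            preds[te] = model.predict_affinity(sub.iloc[te], alleles)
        report.results.append(AlleleResult(
            allele=allele, n_peptides=len(sub),
            auc=roc_auc(preds, labels), roc=roc_points(preds, labels),
            supertype=(supertypes or {}).get(allele, "")))
    return report


def evaluate_leave_one_allele_out(df: pd.DataFrame,
                                  alleles: dict[str, AlleleSequence],
                                  model_factory,
                                  supertypes: SupertypeMap | None = None,
                                  seed: int = 0,
                                  restrict_locus: bool = True) -> EvalReport:
    """Leave-one-allele-out validation.

    For each allele X the model trains on every record of every *other*
    allele (same locus by default) and is scored on X's records; X's own
    data never enters training.
    """
    allele_names = sorted(df["allele"].unique())
    if len(allele_names) < 2:
        raise ValueError("leave-one-allele-out needs at least 2 alleles")
    report = EvalReport(mode="loo", seed=seed)
    for k, allele in enumerate(allele_names):
        test = df[df["allele"] == allele]
        labels = test["binder"].to_numpy()
        if labels.all() or not labels.any():
            logger.warning("held-out allele %s has a single class; skipped",
                           allele)
            continue
        train_df = df[df["allele"] != allele]
        if restrict_locus:
            locus = allele[:1]
            train_df = train_df[train_df["allele"].str.startswith(locus)]
        if train_df.empty:
            logger.warning("no training records for held-out allele %s",
                           allele)
            continue
        model = model_factory(_subseed(seed, k))
        model.fit(train_df.reset_index(drop=True), alleles)
        preds = model.predict_affinity(test, alleles)
        report.results.append(AlleleResult(
            allele=allele, n_peptides=len(test),
            auc=roc_auc(preds, labels), roc=roc_points(preds, labels),
            supertype=(supertypes or {}).get(allele, "")))
    return report
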