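"""Composite genotyping: learn which genotyper to trust per locus and field.

No single HLA genotyper is the most accurate everywhere, but which one
is best is largely predictable from which tools produced a valid call at
a given locus and field. A decision tree is trained on
presence/absence-of-a-valid-genotype features (one per genotyper) plus
one-hot locus and field level, with the highest-accuracy genotyper as
the label; the composite genotype then copies, per sample x locus x
field, the call of the selected genotyper (falling back down a fixed
priority order when the selected tool has no call there). Training uses
a 70/30 split with cross-validated cost-complexity pruning; holdout
quality is reported as accuracy and Hand & Till multiclass AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .callset import GenotypeCallset
from .concordance import ConcordanceResult, count_correct
from .drb_copynumber import hand_till_auc
from .hla_model import LocusGenotype

__all__ = [
    "DEFAULT_PRIORITY",
    "SelectorInstance",
    "SelectorModel",
    "build_selector_instances",
    "train_selector",
    "assemble_composite",
    "composite_name",
]

#: accuracy-tie priority, fastest tool first
DEFAULT_PRIORITY = ("arcasHLA", "OptiType", "PHLAT", "HLAminer")


@dataclass(frozen=True)
class SelectorInstance:
    """One training/prediction unit: sample x locus x field level.

    ``availability`` maps genotyper -> bool ("produced a valid genotype
    here": a non-empty call with at least one allele typed to this field
    depth). ``label`` (training only) is the highest-accuracy available
    genotyper, ties broken by priority order.
    """

    sample_id: str
    locus: str
    field_level: int
    availability: dict[str, bool]
    label: str | None = None


def _available(gt: LocusGenotype, field_level: int) -> bool:
    return (not gt.is_empty) and gt.max_depth() >= field_level


def build_selector_instances(
    callset: GenotypeCallset,
    truth: GenotypeCallset,
    field_levels: list[int],
    *,
    roster: tuple[str, ...] | None = None,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    truth_genotyper: str = "truth",
) -> list[SelectorInstance]:
    """Label each sample x locus x field with its best available genotyper.

    Slots where no genotyper in the roster produced a valid call are
    skipped (nothing to select). Ties at equal accuracy go to the first
    genotyper in ``priority``; roster members missing from ``priority``
    rank after it, alphabetically.
    """
    roster = tuple(roster) if roster is not None else callset.genotypers
    if not roster:
        raise ValueError("empty genotyper roster")
    shared = sorted(set(callset.samples) & {k[0] for k in truth.calls})
    if not shared:
        raise ValueError("no overlapping samples between callset and truth")
    order = [g for g in priority if g in roster] + sorted(
        g for g in roster if g not in priority
    )
    instances: list[SelectorInstance] = []
    truth_loci = truth.loci
    for sample_id in shared:
        for locus in truth_loci:
            t = truth.get(sample_id, truth_genotyper, locus)
            if t.is_empty:
                continue
            for level in field_levels:
                avail = {}
                acc = {}
                for g in roster:
                    p = callset.get(sample_id, g, locus)
                    avail[g] = _available(p, level)
                    if avail[g]:
                        nc, ni, na = count_correct(t, p, level)
                        acc[g] = ConcordanceResult(
                            sample_id, locus, level, nc, ni, na
                        ).accuracy
                if not acc:
                    continue
                best = max(acc.values())
                label = next(g for g in order if acc.get(g) == best)
                instances.append(
                    SelectorInstance(sample_id, locus, level, avail, label)
                )
    return instances


@dataclass
class SelectorModel:
    """Fitted decision-tree genotyper selector."""

    tree: DecisionTreeClassifier
    feature_columns: list[str]
    roster: tuple[str, ...]
    priority: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def _featurize(self, instances: list[SelectorInstance]) -> pd.DataFrame:
        rows = []
        for inst in instances:
            row = {f"locus={inst.locus}": 1, f"field={inst.field_level}": 1}
            for g in self.roster:
                row[f"avail_{g}"] = int(inst.availability.get(g, False))
            rows.append(row)
        df = pd.DataFrame(rows).fillna(0).astype(int)
        return df.reindex(columns=self.feature_columns, fill_value=0)

    def select(self, inst: SelectorInstance) -> str | None:
        """Pick a genotyper for one slot, never an unavailable one.

        The tree's class probabilities are masked to available genotypers;
        if the mass lands entirely on unavailable tools, fall back down the
        priority order. Returns None when nothing is available.
        """
        available = [g for g in self.roster if inst.availability.get(g, False)]
        if not available:
            return None
        X = self._featurize([inst])
        proba = self.tree.predict_proba(X.to_numpy())[0]
        classes = list(self.tree.classes_)
        order = [g for g in self.priority if g in self.roster] + sorted(
            g for g in self.roster if g not in self.priority
        )
        best, best_p = None, -1.0
        for g in available:
            p = proba[classes.index(g)] if g in classes else 0.0
            # ties resolved by priority rank
            if p > best_p + 1e-12:
                best, best_p = g, p
        if best_p <= 0.0:
            return next(g for g in order if g in available)
        # re-scan in priority order to break exact ties deterministically
        for g in order:
            if g in available:
                p = proba[classes.index(g)] if g in classes else 0.0
                if abs(p - best_p) <= 1e-12:
                    return g
        return best


def train_selector(
    instances: list[SelectorInstance],
    *,
    train_fraction: float = 0.70,
    cv_folds: int = 10,
    seed: int = 0,
    max_depth: int = 8,
    min_samples_leaf: int = 5,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> SelectorModel:
    """Fit the decision-tree selector on a 70/30 split.

    Cost-complexity pruning strength is tuned by cross-validation over
    the tree's own pruning path. A single distinct label yields a
    degenerate constant model, recorded with a warning in the metadata.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    labeled = [i for i in instances if i.label is not None]
    if not labeled:
        raise ValueError("no labeled instances")
    roster = tuple(
        sorted({g for i in labeled for g in i.availability})
    )
    feature_columns = (
        sorted({f"locus={i.locus}" for i in labeled})
        + sorted({f"field={i.field_level}" for i in labeled})
        + [f"avail_{g}" for g in roster]
    )
    model = SelectorModel(
        tree=DecisionTreeClassifier(
            max_depth=max_depth, min_samples_leaf=min_samples_leaf, random_state=seed
        ),
        feature_columns=feature_columns,
        roster=roster,
        priority=priority,
    )
    X = model._featurize(labeled).to_numpy()
    y = np.array([i.label for i in labeled])
    labels, counts = np.unique(y, return_counts=True)
    meta: dict = {"seed": seed, "n_instances": len(labeled), "labels": labels.tolist()}
    if len(labels) < 2:
        model.tree.fit(X, y)
        meta["warning"] = "single label; degenerate constant selector"
        meta["holdout_accuracy"] = 1.0
        model.metadata = meta
        return model
    strat = y if counts.min() >= 2 else None
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=strat
    )
    tree = model.tree
    tree.fit(X[train_idx], y[train_idx])
    # prune: CV over the fitted tree's own alpha path
    alphas = np.unique(tree.cost_complexity_pruning_path(X[train_idx], y[train_idx]).ccp_alphas)
    alphas = alphas[alphas >= 0][:20]
    train_counts = np.unique(y[train_idx], return_counts=True)[1]
    folds = int(min(cv_folds, train_counts.min()))
    if len(alphas) > 1 and folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        search = GridSearchCV(
            DecisionTreeClassifier(
                max_depth=max_depth, min_samples_leaf=min_samples_leaf, random_state=seed
            ),
            {"ccp_alpha": alphas},
            cv=cv,
            scoring="accuracy",
        )
        search.fit(X[train_idx], y[train_idx])
        model.tree = search.best_estimator_
        meta["ccp_alpha"] = float(search.best_params_["ccp_alpha"])
        meta["cv_folds"] = folds
        meta["cv_score"] = float(search.best_score_)
    y_pred = model.tree.predict(X[test_idx])
    meta["holdout_accuracy"] = float(np.mean(y_pred == y[test_idx]))
    if len(np.unique(y[test_idx])) >= 2:
        proba = model.tree.predict_proba(X[test_idx])
        meta["holdout_auc"] = hand_till_auc(
            proba, y[test_idx], classes=list(model.tree.classes_)
        )
    model.metadata = meta
    return model


def composite_name(roster: tuple[str, ...]) -> str:
    """'composite(AOP)'-style label from the roster's initials."""
    initials = "".join(g[0].upper() for g in roster)
    return f"composite({initials})"


def assemble_composite(
    callset: GenotypeCallset,
    selector: SelectorModel,
    field_levels: list[int],
    *,
    loci: tuple[str, ...] | None = None,
) -> dict[int, GenotypeCallset]:
    """Assemble the composite genotype, one callset per field level.

    Per sample x locus x field, the selected genotyper's call is copied
    and truncated to that field. When no roster genotyper produced a
    valid call the composite slot stays absent (scored 0 accuracy
    downstream). Calls never come from a tool that produced none.
    """
    loci = loci if loci is not None else callset.loci
    name = composite_name(selector.roster)
    out: dict[int, GenotypeCallset] = {}
    for level in field_levels:
        cs = GenotypeCallset()
        for sample_id in callset.samples:
            for locus in loci:
                avail = {
                    g: _available(callset.get(sample_id, g, locus), level)
                    for g in selector.roster
                }
                inst = SelectorInstance(sample_id, locus, level, avail)
                chosen = selector.select(inst)
                if chosen is None:
                    continue
                gt = callset.get(sample_id, chosen, locus).truncated(level)
                cs.set(sample_id, name, locus, gt)
        out[level] = cs
    return out
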