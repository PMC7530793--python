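"""Threshold-based cell phenotyping with sequential binary hierarchy.

Each marker gets one threshold on one compartment measurement.  The
hierarchical classifier walks the markers in a *detection order*: at each
step, unclaimed cells above that marker's threshold receive the step's base
class, while already-classified cells above threshold are relabelled only
if a compound rule exists for (their current class, the marker) — otherwise
their class is retained and the positivity ignored.  Compound classes are
tagged expected or unexpected; stripping the unexpected-tagged rules yields
the original "script 1", the full tree is "script 2".  Because strongly
expressed markers detected early mask weaker co-expressed neighbours in
dense regions, the detection order materially changes MP1 results; a
nonhierarchical multilabel classifier (order-irrelevant by construction)
and a trained random-forest mode are provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from . import panels
from .errors import ConfigurationError

__all__ = [
    "MarkerThreshold",
    "PhenotypeTree",
    "CompoundRule",
    "PhenotypeCall",
    "UNCLASSIFIED",
    "measurement_column",
    "default_thresholds",
    "derive_threshold",
    "classify_singleplex",
    "classify_hierarchical",
    "classify_multilabel",
    "classify_learned",
    "order_sweep",
    "compare_scripts",
    "mp1_tree",
    "mp2_tree",
    "default_orders",
    "label_implies_positive",
    "marker_positive_fractions",
]

UNCLASSIFIED = "unclassified"


def measurement_column(marker: str) -> str:
    """Stable column carrying the single measurement thresholded per marker."""
    comp = panels.MARKER_COMPARTMENT[marker]
    return f"{marker}_{comp}_mean"


@dataclass(frozen=True)
class MarkerThreshold:
    marker: str
    compartment: str
    value: float
    provenance: str = "manual"  # manual | auto

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ConfigurationError("threshold must be positive")

    @property
    def column(self) -> str:
        return f"{self.marker}_{self.compartment}_mean"


def default_thresholds(panel: str, value: float = 10.0) -> dict[str, MarkerThreshold]:
    """Manual thresholds at `value` counts for every panel marker but DAPI.

    10 counts sits midway between the autofluorescence-level background
    (~2 counts) and the calibrated positive signal (20-25 counts),
    mirroring the >10:1 signal-to-background rule used at optimisation.
    """
    return {
        m: MarkerThreshold(m, panels.MARKER_COMPARTMENT[m], value, "manual")
        for m in panels.panel_markers(panel)
        if m != "DAPI"
    }


def derive_threshold(
    cells: pd.DataFrame,
    marker: str,
    method: str,
    manual_value: float | None = None,
    reference_positive_fraction: float | None = None,
) -> MarkerThreshold:
    """Set a marker threshold.

    * ``manual``: the configured value, verbatim.
    * ``quantile-match``: the cut whose positive fraction reproduces a
      reference fraction (the chromogenic/ground-truth arm standing in for
      meticulously matched DAB thresholds).
    * ``otsu``: bimodal split of the compartment measurement.
    """
    col = measurement_column(marker)
    if col not in cells.columns:
        raise ConfigurationError(f"measurement column {col!r} missing from cell table")
    values = cells[col].to_numpy(dtype=float)
    comp = panels.MARKER_COMPARTMENT[marker]
    if method == "manual":
        if manual_value is None:
            raise ConfigurationError("manual method requires a value")
        return MarkerThreshold(marker, comp, float(manual_value), "manual")
    if method == "quantile-match":
        if reference_positive_fraction is None:
            raise ConfigurationError("quantile-match requires a reference positive fraction")
        q = float(reference_positive_fraction)
        if not (0.0 <= q <= 1.0):
            raise ConfigurationError("reference fraction must lie in [0, 1]")
        n = len(values)
        if n == 0:
            raise ConfigurationError("empty cell table")
        desc = np.sort(values)[::-1]
        k = int(round(q * n))  # number of positives wanted
        if k <= 0:
            thr = desc[0] + 1.0
        elif k >= n:
            thr = max(desc[-1] / 2.0, np.finfo(float).tiny)
        else:
            thr = 0.5 * (desc[k - 1] + desc[k])
            if thr <= 0:
                thr = np.finfo(float).tiny
        return MarkerThreshold(marker, comp, float(thr), "auto")
    if method == "otsu":
        return MarkerThreshold(marker, comp, float(threshold_otsu(values)), "auto")
    raise ConfigurationError(f"unknown threshold method {method!r}")


def _positivity(cells: pd.DataFrame, thresholds: dict[str, MarkerThreshold]) -> pd.DataFrame:
    cols = {}
    for m, t in thresholds.items():
        if t.column not in cells.columns:
            raise ConfigurationError(f"measurement column {t.column!r} missing from cell table")
        cols[m] = cells[t.column].to_numpy(dtype=float) > t.value  # strict: ties negative
    return pd.DataFrame(cols, index=cells.index)


def classify_singleplex(
    cells: pd.DataFrame, marker: str, threshold: MarkerThreshold
) -> pd.Series:
    """Binary call for one marker, independent of all others."""
    pos = cells[threshold.column].to_numpy(dtype=float) > threshold.value
    return pd.Series(pos, index=cells.index, name=f"{marker}_positive")


# ---------------------------------------------------------------------------
# decision trees


@dataclass(frozen=True)
class CompoundRule:
    existing_class: str
    marker: str
    new_class: str
    expected: bool = True


@dataclass
class PhenotypeTree:
    """Base class per marker step plus compound relabelling rules."""

    base_classes: dict[str, str]  # marker -> class for unclaimed positives
    compound_rules: list[CompoundRule] = field(default_factory=list)
    unexpected_classes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen = {}
        for r in self.compound_rules:
            key = (r.existing_class, r.marker)
            if key in seen:
                raise ConfigurationError(f"duplicate compound rule for {key}")
            seen[key] = r
        self._rule_map = seen

    @property
    def markers(self) -> list[str]:
        return list(self.base_classes)

    def vocabulary(self) -> set[str]:
        vocab = set(self.base_classes.values())
        vocab.update(r.new_class for r in self.compound_rules)
        return vocab

    def rule_for(self, existing_class: str, marker: str) -> CompoundRule | None:
        return self._rule_map.get((existing_class, marker))

    def without_unexpected(self) -> "PhenotypeTree":
        """Script 1: the tree with unexpected-tagged compound rules stripped."""
        return PhenotypeTree(
            dict(self.base_classes),
            [r for r in self.compound_rules if r.expected],
            set(self.unexpected_classes),
        )

    def validate_order(self, order: list[str]) -> None:
        if sorted(order) != sorted(self.markers):
            raise ConfigurationError(
                f"detection order {order} is not a permutation of tree markers {self.markers}"
            )
        if len(set(order)) != len(order):
            raise ConfigurationError("detection order contains repeats")


def mp1_tree() -> PhenotypeTree:
    """Default MP1 decision tree.

    Expected vocabulary: CK+, CD20+, CD3+/CD4+, CD3+/CD8+, CD3+ (CD4/CD8
    null).  Unexpected classes capture dual positives seen in dense immune
    regions (CD4+/CD8+) and T-lineage-marker positives without CD3.  Rules
    are written for both CD3-before and CD3-after orders so one tree serves
    every detection order in a sweep; rules unreachable under a given order
    are simply inert.
    """
    expected = [
        CompoundRule("CD3-/CD4+", "CD3", "CD3+/CD4+"),
        CompoundRule("CD3-/CD8+", "CD3", "CD3+/CD8+"),
        CompoundRule("CD3+", "CD4", "CD3+/CD4+"),
        CompoundRule("CD3+", "CD8", "CD3+/CD8+"),
    ]
    unexpected = [
        CompoundRule("CD3+/CD4+", "CD8", "CD4+/CD8+", expected=False),
        CompoundRule("CD3-/CD4+", "CD8", "CD4+/CD8+", expected=False),
        CompoundRule("CD3+/CD8+", "CD4", "CD4+/CD8+", expected=False),
        CompoundRule("CD3-/CD8+", "CD4", "CD4+/CD8+", expected=False),
    ]
    return PhenotypeTree(
        base_classes={
            "CK": "CK+",
            "CD4": "CD3-/CD4+",
            "CD3": "CD3+",
            "CD20": "CD20+",
            "CD8": "CD3-/CD8+",
        },
        compound_rules=expected + unexpected,
        unexpected_classes={"CD4+/CD8+", "CD3-/CD4+", "CD3-/CD8+"},
    )


def mp2_tree() -> PhenotypeTree:
    """Default MP2 tree; the only unexpected class is CD4+/CD68+."""
    return PhenotypeTree(
        base_classes={"CK": "CK+", "CD68": "CD68+", "CD4": "CD4+", "FOXP3": "FOXP3+"},
        compound_rules=[
            CompoundRule("CD4+", "FOXP3", "CD4+/FOXP3+"),
            CompoundRule("FOXP3+", "CD4", "CD4+/FOXP3+"),
            CompoundRule("CD68+", "CD4", "CD4+/CD68+", expected=False),
            CompoundRule("CD4+", "CD68", "CD4+/CD68+", expected=False),
        ],
        unexpected_classes={"CD4+/CD68+"},
    )


def default_tree(panel: str) -> PhenotypeTree:
    panels.check_panel(panel)
    return mp1_tree() if panel == panels.MP1 else mp2_tree()


def default_orders(panel: str) -> dict[str, list[str]]:
    """Shipped detection orders.

    For MP1 the first (naive, CD20-first) and final (CK > CD4 > CD3 > CD20 >
    CD8) orders are as reported; the four intermediates are reconstructions
    forming a plausible refinement path.  MP2 order effects are negligible,
    so a single order plus one permutation are shipped.
    """
    if panels.check_panel(panel) == panels.MP1:
        return {
            "order1-cd20-first": ["CD20", "CD3", "CK", "CD8", "CD4"],
            "order2": ["CD20", "CD8", "CD3", "CD4", "CK"],
            "order3": ["CK", "CD20", "CD3", "CD4", "CD8"],
            "order4": ["CK", "CD3", "CD4", "CD20", "CD8"],
            "order5-cd20-last": ["CK", "CD4", "CD3", "CD8", "CD20"],
            "final": ["CK", "CD4", "CD3", "CD20", "CD8"],
        }
    return {
        "default": ["CK", "CD68", "CD4", "FOXP3"],
        "reversed": ["FOXP3", "CD4", "CD68", "CK"],
    }


def tree_to_yaml(tree: PhenotypeTree, orders: dict[str, list[str]] | None = None) -> str:
    """Serialise a tree (and optional named orders) to YAML."""
    import yaml

    payload: dict = {
        "base_classes": dict(tree.base_classes),
        "compound_rules": [
            {
                "existing_class": r.existing_class,
                "marker": r.marker,
                "new_class": r.new_class,
                "expected": r.expected,
            }
            for r in tree.compound_rules
        ],
        "unexpected_classes": sorted(tree.unexpected_classes),
    }
    if orders:
        payload["orders"] = {k: list(v) for k, v in orders.items()}
    return yaml.safe_dump(payload, sort_keys=False)


def tree_from_yaml(text: str) -> tuple[PhenotypeTree, dict[str, list[str]]]:
    import yaml

    payload = yaml.safe_load(text)
    tree = PhenotypeTree(
        base_classes=dict(payload["base_classes"]),
        compound_rules=[CompoundRule(**r) for r in payload.get("compound_rules", [])],
        unexpected_classes=set(payload.get("unexpected_classes", [])),
    )
    return tree, {k: list(v) for k, v in payload.get("orders", {}).items()}


# ---------------------------------------------------------------------------
# classifiers


@dataclass
class PhenotypeCall:
    """Per-cell class labels plus an audit trail of which step/rule fired."""

    labels: pd.Series  # index = cells.index, values = class labels
    audit: dict = field(default_factory=dict)

    def fractions(self, of_classified: bool = True) -> pd.Series:
        lab = self.labels
        if of_classified:
            lab = lab[lab != UNCLASSIFIED]
        if len(lab) == 0:
            return pd.Series(dtype=float)
        return lab.value_counts(normalize=True).sort_index()


def classify_hierarchical(
    cells: pd.DataFrame,
    thresholds: dict[str, MarkerThreshold],
    order: list[str],
    tree: PhenotypeTree,
) -> PhenotypeCall:
    """Sequential binary hierarchical classification along a detection order."""
    tree.validate_order(order)
    missing = [m for m in order if m not in thresholds]
    if missing:
        raise ConfigurationError(f"no thresholds for markers {missing}")
    P = _positivity(cells, {m: thresholds[m] for m in order})
    labels = pd.Series(UNCLASSIFIED, index=cells.index, dtype=object)
    audit: dict = {i: [] for i in cells.index}
    for m in order:
        pos = P[m].to_numpy()
        base = tree.base_classes[m]
        unclaimed = (labels == UNCLASSIFIED).to_numpy()
        newly = unclaimed & pos
        for i in cells.index[newly]:
            audit[i].append(f"{m}: base -> {base}")
        labels[newly] = base
        # relabel claimed positives through compound rules
        claimed_pos = cells.index[(~unclaimed) & pos]
        for i in claimed_pos:
            rule = tree.rule_for(labels[i], m)
            if rule is not None:
                audit[i].append(f"{m}: {labels[i]} -> {rule.new_class}"
                                + ("" if rule.expected else " [unexpected]"))
                labels[i] = rule.new_class
            else:
                audit[i].append(f"{m}: positive ignored (kept {labels[i]})")
    return PhenotypeCall(labels.rename("phenotype"), audit)


def classify_multilabel(
    cells: pd.DataFrame,
    thresholds: dict[str, MarkerThreshold],
    label_map: dict[frozenset, str] | None = None,
) -> PhenotypeCall:
    """Nonhierarchical classification: the per-cell positive-marker set,
    mapped to the phenotype vocabulary where a mapping exists.  The marker
    evaluation order is provably irrelevant (set semantics)."""
    if label_map is None:
        label_map = {}
    P = _positivity(cells, thresholds)
    markers = list(thresholds)
    labels = []
    audit: dict = {}
    for i in cells.index:
        pos = frozenset(m for m in markers if P.at[i, m])
        if pos in label_map:
            lab = label_map[pos]
        elif not pos:
            lab = UNCLASSIFIED
        else:
            lab = "/".join(f"{m}+" for m in markers if m in pos)  # raw set label
        labels.append(lab)
        audit[i] = [f"positive set: {sorted(pos)}"]
    return PhenotypeCall(pd.Series(labels, index=cells.index, name="phenotype"), audit)


def classify_learned(
    cells: pd.DataFrame,
    training_labels: pd.Series,
    feature_set: list[str] | None = None,
    seed: int = 0,
) -> PhenotypeCall:
    """Random-forest classification over multiple measurements.

    Trained on the painted subset (`training_labels`, indexed into `cells`),
    applied to every cell; the seed fixes training so calls are reproducible.
    """
    from sklearn.ensemble import RandomForestClassifier

    if training_labels.nunique() < 2:
        raise ConfigurationError("training requires at least two classes")
    if feature_set is None:
        feature_set = [c for c in cells.columns if c.endswith("_mean")]
    X_train = cells.loc[training_labels.index, feature_set].to_numpy()
    clf = RandomForestClassifier(n_estimators=100, random_state=int(seed) & 0x7FFFFFFF)
    clf.fit(X_train, training_labels.to_numpy())
    pred = clf.predict(cells[feature_set].to_numpy())
    labels = pd.Series(pred, index=cells.index, name="phenotype")
    audit = {"features": list(feature_set), "n_train": int(len(training_labels))}
    return PhenotypeCall(labels, audit)


# ---------------------------------------------------------------------------
# class-label algebra and analyses


def label_implies_positive(label: str, marker: str) -> bool:
    """Whether a class label asserts positivity for `marker` (token parse)."""
    if label == UNCLASSIFIED:
        return False
    return any(tok == f"{marker}+" for tok in label.split("/"))


def marker_positive_fractions(labels: pd.Series, markers: list[str]) -> pd.Series:
    """Fraction of all cells whose class label implies each marker positive."""
    n = len(labels)
    if n == 0:
        return pd.Series(0.0, index=markers)
    return pd.Series(
        {m: sum(label_implies_positive(l, m) for l in labels) / n for m in markers}
    )


@dataclass
class OrderSweepResult:
    class_fractions: pd.DataFrame  # order x class, over classified cells
    singleplex_fractions: pd.Series  # marker -> fraction of all cells positive
    deviations: pd.Series  # order -> summed |hier - singleplex| over markers
    calls: dict[str, PhenotypeCall]


def order_sweep(
    cells: pd.DataFrame,
    thresholds: dict[str, MarkerThreshold],
    tree: PhenotypeTree,
    orders: dict[str, list[str]],
) -> OrderSweepResult:
    """Run the hierarchical classifier under each detection order.

    Reports per-order class fractions (over classified cells) and each
    order's summed absolute deviation, across markers, between the fraction
    of cells its classes imply positive and the singleplex (independent
    threshold) positive fraction.
    """
    markers = tree.markers
    single = pd.Series(
        {
            m: float(classify_singleplex(cells, m, thresholds[m]).mean())
            for m in markers
        }
    )
    rows, devs, calls = {}, {}, {}
    for name, order in orders.items():
        call = classify_hierarchical(cells, thresholds, order, tree)
        calls[name] = call
        rows[name] = call.fractions(of_classified=True)
        hier = marker_positive_fractions(call.labels, markers)
        devs[name] = float((hier - single).abs().sum())
    frac = pd.DataFrame(rows).T.fillna(0.0)
    return OrderSweepResult(frac, single, pd.Series(devs), calls)


@dataclass
class ScriptComparison:
    report: pd.DataFrame  # per context x script-1 class: counts and reassigned
    reassigned: pd.DataFrame  # cell-level: id/index, from, to, context
    script1: PhenotypeCall
    script2: PhenotypeCall

    @property
    def empty(self) -> bool:
        return len(self.reassigned) == 0


def compare_scripts(
    cells: pd.DataFrame,
    thresholds: dict[str, MarkerThreshold],
    order: list[str],
    tree_with_unexpected: PhenotypeTree,
    contexts: pd.Series | None = None,
) -> ScriptComparison:
    """Script 1 (expected classes only) vs script 2 (full tree).

    Script 2 can only relabel cells script 1 classified; the unclassified
    sets are identical by construction.  The report counts, per tissue
    context and script-1 class, how many cells the unexpected rules
    reassigned and to what.
    """
    s1 = classify_hierarchical(cells, thresholds, order, tree_with_unexpected.without_unexpected())
    s2 = classify_hierarchical(cells, thresholds, order, tree_with_unexpected)
    if contexts is None:
        contexts = pd.Series("all", index=cells.index)
    moved = s1.labels != s2.labels
    reassigned = pd.DataFrame(
        {
            "from_class": s1.labels[moved],
            "to_class": s2.labels[moved],
            "context": contexts[moved],
        }
    )
    rows = []
    for ctx in sorted(contexts.unique()):
        in_ctx = contexts == ctx
        for cls in sorted(s1.labels[in_ctx].unique()):
            sel = in_ctx & (s1.labels == cls)
            n = int(sel.sum())
            n_moved = int((sel & moved).sum())
            rows.append(
                {
                    "context": ctx,
                    "script1_class": cls,
                    "n_cells": n,
                    "n_reassigned": n_moved,
                    "fraction_reassigned": n_moved / n if n else 0.0,
                }
            )
    return ScriptComparison(pd.DataFrame(rows), reassigned, s1, s2)
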