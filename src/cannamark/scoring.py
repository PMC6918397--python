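"""Consensus-based discriminant scores with AUC-optimized weights.

A sample's score is a weighted sum of per-locus points. At a SNP locus a
sample earns +1 if its allele equals the drug-class consensus (modal)
allele, -1 if it equals the fiber-class consensus, and 0 otherwise (so a
heterozygous code matching neither consensus scores 0). At an indel locus
the points are 1 if the variant is present and 0 otherwise, with the sign
carried by the weight — the published deletion/insertion score assigns
+1.1 to the deletion and -1 to the insertion, so its attainable values are
exactly {-1, 0, 0.1, 1.1}. Classification uses the strict rule
``score > threshold ⇒ drug`` with a default threshold of 0.

Weights are chosen to maximize the ROC area (AUC, the Mann-Whitney
probability that a random drug-class score exceeds a random fiber-class
score, ties counting one half) by deterministic greedy forward selection
of loci plus a per-step coordinate grid search over weights in [-2, 2]
(step 0.1), under the constraint that at most a configured minority of the
k weights are negative. Threshold performance is evaluated with stratified
percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .calling import GenotypeMatrix

#: fixed allele ordering used to break consensus ties (lower wins)
_ALLELE_ORDER = {a: i for i, a in enumerate(
    list("ACGT") + sorted("RYSWKMBDHVN") + ["del", "ins", "ref"]
)}

WEIGHT_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)

#: published indel weights: deletion +1.1, insertion -1
INDEL_WEIGHTS = {"deletion": 1.1, "insertion": -1.0}


def _allele_rank(allele: str) -> int:
    return _ALLELE_ORDER.get(allele, len(_ALLELE_ORDER))


@dataclass
class ScoreSpec:
    """Selected loci, per-locus weights and the decision threshold."""

    loci: list[str]
    weights: list[float]
    threshold: float = 0.0
    auc: float | None = None

    def __post_init__(self):
        if len(self.loci) != len(self.weights) or not self.loci:
            raise ValueError("need equally many loci and weights, at least one")

    @property
    def k(self) -> int:
        return len(self.loci)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"loci": self.loci, "weights": self.weights,
             "threshold": self.threshold, "auc": self.auc},
            indent=2, sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "ScoreSpec":
        try:
            data = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                data = json.load(fh)
        return cls(**data)


@dataclass
class EvalResult:
    auc: float
    sensitivity: float
    specificity: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }


def consensus_profile(matrix: GenotypeMatrix, loci) -> pd.DataFrame:
    """Modal allele per class at each requested locus.

    Ties are broken by the fixed allele ordering (A<C<G<T<IUPAC<del/ins<ref)
    with a warning. Returns a DataFrame indexed by locus key with
    ``drug_allele`` and ``fiber_allele`` columns.
    """
    loci = list(loci)
    missing = [k for k in loci if k not in matrix.cells.columns]
    if missing:
        raise KeyError(f"loci absent from matrix: {missing}")
    drug = matrix.cells.loc[matrix.labels == "drug", loci]
    fiber = matrix.cells.loc[matrix.labels == "fiber", loci]
    if drug.empty or fiber.empty:
        raise ValueError("both classes must be non-empty")
    rows = {}
    for key in loci:
        alleles = {}
        for name, block in (("drug_allele", drug), ("fiber_allele", fiber)):
            counts = block[key].value_counts()
            top = counts.max()
            modal = sorted(counts[counts == top].index, key=_allele_rank)
            if len(modal) > 1:
                warnings.warn(
                    f"consensus tie at {key} ({name}): {modal}; "
                    f"taking {modal[0]!r} by allele ordering"
                )
            alleles[name] = modal[0]
        rows[key] = alleles
    return pd.DataFrame.from_dict(rows, orient="index").loc[loci]


def locus_points(cell: str, drug_allele: str, fiber_allele: str) -> int:
    """Three-way consensus rule: +1 drug consensus, -1 fiber consensus, else 0."""
    if drug_allele == fiber_allele:
        return 0  # non-discriminating locus
    if cell == drug_allele:
        return 1
    if cell == fiber_allele:
        return -1
    return 0


def _points_vector(matrix: GenotypeMatrix, key: str, profile: pd.DataFrame) -> np.ndarray:
    """Per-sample points at one locus (consensus rule for SNPs, presence for indels)."""
    kind = matrix.loci.loc[key, "kind"]
    col = matrix.cells[key]
    if kind in ("deletion", "insertion"):
        return col.isin(("del", "ins")).to_numpy(dtype=float)
    if key not in profile.index:
        raise KeyError(f"no consensus profile at locus {key}")
    drug_a = profile.loc[key, "drug_allele"]
    fiber_a = profile.loc[key, "fiber_allele"]
    return np.array([locus_points(c, drug_a, fiber_a) for c in col], dtype=float)


def sample_score(row: pd.Series, spec: ScoreSpec, profile: pd.DataFrame,
                 loci_kinds: pd.Series) -> float:
    """Score a single sample row under a spec; missing cells score 0 with a warning."""
    total = 0.0
    for key, w in zip(spec.loci, spec.weights):
        if key not in row.index or pd.isna(row[key]):
            warnings.warn(f"missing genotype at {key}; scored as 0 points")
            continue
        cell = row[key]
        kind = loci_kinds[key]
        if kind in ("deletion", "insertion"):
            pts = 1.0 if cell in ("del", "ins") else 0.0
        else:
            pts = locus_points(
                cell, profile.loc[key, "drug_allele"], profile.loc[key, "fiber_allele"]
            )
        total += w * pts
    return total


def score_samples(matrix: GenotypeMatrix, spec: ScoreSpec,
                  profile: pd.DataFrame) -> pd.Series:
    """Vectorized scores for every sample in the matrix."""
    total = np.zeros(len(matrix.cells))
    for key, w in zip(spec.loci, spec.weights):
        total += w * _points_vector(matrix, key, profile)
    return pd.Series(total, index=matrix.cells.index, name="score")


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random drug score > random fiber score), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    drug = scores[labels == "drug"]
    fiber = scores[labels == "fiber"]
    if drug.size == 0 or fiber.size == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)
    r_drug = ranks[labels == "drug"].sum()
    n1, n0 = drug.size, fiber.size
    return float((r_drug - n1 * (n1 + 1) / 2) / (n1 * n0))


def indel_score_spec(matrix: GenotypeMatrix, threshold: float = 0.0) -> ScoreSpec:
    """The published deletion/insertion score (+1.1 del, -1 ins) on a matrix."""
    del_keys = [k for k in matrix.cells.columns if matrix.loci.loc[k, "kind"] == "deletion"]
    ins_keys = [k for k in matrix.cells.columns if matrix.loci.loc[k, "kind"] == "insertion"]
    if not del_keys or not ins_keys:
        raise ValueError("matrix has no deletion/insertion loci")
    return ScoreSpec(
        loci=[del_keys[0], ins_keys[0]],
        weights=[INDEL_WEIGHTS["deletion"], INDEL_WEIGHTS["insertion"]],
        threshold=threshold,
    )


def optimize_weights(
    matrix: GenotypeMatrix,
    profile: pd.DataFrame,
    k: int,
    allow_negative: int | None = None,
    grid: np.ndarray = WEIGHT_GRID,
) -> ScoreSpec:
    """Greedy AUC-maximizing selection of k loci with grid-searched weights.

    Candidates are the loci of ``profile`` plus any indel loci in the
    matrix. At each step the (locus, weight) pair with the largest AUC gain
    is added (weights from the grid, nonzero at selection), then one
    coordinate pass re-optimizes every weight on the grid including zero —
    so the achieved AUC never decreases as k grows. At most
    ``allow_negative`` weights may be negative (default: 1 when k = 2, else
    floor((k-1)/2), reading "most of the k weights non-negative"
    permissively at k = 2 to admit the published indel pair).
    """
    candidates = list(profile.index) + [
        key for key in matrix.cells.columns
        if matrix.loci.loc[key, "kind"] in ("deletion", "insertion")
        and key not in set(profile.index)
    ]
    if k < 1 or k > len(candidates):
        raise ValueError(f"k must be between 1 and {len(candidates)}")
    if allow_negative is None:
        allow_negative = 1 if k == 2 else (k - 1) // 2
    labels = matrix.labels.to_numpy()
    points = {key: _points_vector(matrix, key, profile) for key in candidates}

    selected: list[str] = []
    weights: list[float] = []
    base = np.zeros(len(matrix.cells))
    best_auc = -np.inf
    for _ in range(k):
        n_neg = sum(1 for w in weights if w < 0)
        step_best = None  # (auc, locus, weight)
        for key in candidates:
            if key in selected:
                continue
            pts = points[key]
            for w in grid:
                if w == 0.0:
                    continue
                if w < 0 and n_neg + 1 > allow_negative:
                    continue
                a = auc(base + w * pts, labels)
                if step_best is None or a > step_best[0] + 1e-12:
                    step_best = (a, key, float(w))
        if step_best is None:
            raise ValueError("no admissible locus/weight available")
        _, key, w = step_best
        selected.append(key)
        weights.append(w)
        # coordinate refinement: one pass over all weights, zero admitted
        for i, key_i in enumerate(selected):
            others = sum(
                w_j * points[k_j]
                for j, (k_j, w_j) in enumerate(zip(selected, weights)) if j != i
            )
            if isinstance(others, int):
                others = np.zeros(len(matrix.cells))
            n_neg_others = sum(
                1 for j, w_j in enumerate(weights) if j != i and w_j < 0
            )
            best_w, best_a = weights[i], auc(others + weights[i] * points[key_i], labels)
            for w in grid:
                if w < 0 and n_neg_others + 1 > allow_negative:
                    continue
                a = auc(others + w * points[key_i], labels)
                if a > best_a + 1e-12:
                    best_a, best_w = a, float(w)
            weights[i] = best_w
        base = sum(w_j * points[k_j] for k_j, w_j in zip(selected, weights))
        best_auc = auc(base, labels)
    return ScoreSpec(loci=selected, weights=weights, threshold=0.0, auc=best_auc)


def sensitivity_specificity(scores, labels, threshold: float = 0.0):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    drug = scores[labels == "drug"]
    fiber = scores[labels == "fiber"]
    sens = float((drug > threshold).mean()) if drug.size else np.nan
    spec = float((fiber <= threshold).mean()) if fiber.size else np.nan
    return sens, spec


def evaluate(
    spec: ScoreSpec,
    matrix: GenotypeMatrix,
    profile: pd.DataFrame,
    B: int = 2000,
    seed: int = 0,
) -> EvalResult:
    """Point metrics plus stratified percentile-bootstrap 95% CIs.

    Sensitivity is the fraction of drug samples with score strictly above
    the threshold; specificity the fraction of fiber samples at or below
    it. Bootstrap resampling is stratified by class with ``B`` resamples;
    a metric constant across resamples yields a degenerate CI equal to the
    point estimate.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    scores = score_samples(matrix, spec, profile).to_numpy()
    labels = matrix.labels.to_numpy()
    point_auc = auc(scores, labels)
    sens, spc = sensitivity_specificity(scores, labels, spec.threshold)

    rng = np.random.default_rng(seed)
    idx_drug = np.flatnonzero(labels == "drug")
    idx_fiber = np.flatnonzero(labels == "fiber")
    stats = {"auc": np.empty(B), "sensitivity": np.empty(B), "specificity": np.empty(B)}
    for b in range(B):
        take = np.concatenate([
            rng.choice(idx_drug, size=idx_drug.size, replace=True),
            rng.choice(idx_fiber, size=idx_fiber.size, replace=True),
        ])
        s, l = scores[take], labels[take]
        stats["auc"][b] = auc(s, l)
        se, sp = sensitivity_specificity(s, l, spec.threshold)
        stats["sensitivity"][b] = se
        stats["specificity"][b] = sp
    ci = {
        name: (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
        for name, vals in stats.items()
    }
    return EvalResult(auc=point_auc, sensitivity=sens, specificity=spc, ci=ci)
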