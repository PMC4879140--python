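"""Exhaustive feature-combination search, ranking, and the permutation test.

All C(6,2) = 15 two-feature and C(6,3) = 20 three-feature subsets of the six
epoch features are scored per subject and chromophore with cross-validated
LDA — 70 combinations in total across both chromophores.  The best
combination is compared against the others with an exact paired sign-flip
permutation test on per-subject accuracies: all 2ⁿ sign assignments of the
paired differences are enumerated (128 for 7 subjects) and the one-sided
p-value is the proportion whose mean difference is at least the observed one
(the identity assignment counts, so p ≥ 1/2ⁿ).

The published per-subject accuracy tables for every combination ship as a
checksummed fixture; their cross-subject means (93.0% HbO / 89.9% HbR for
mean+peak) and combination rankings are recomputed from those cells, never
hard-coded.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .classify import CVSpec, cross_validate
from .features import FEATURE_NAMES

__all__ = [
    "ComboSpec",
    "ComboResult",
    "PermutationResult",
    "enumerate_combos",
    "score_all",
    "permutation_test",
    "average_across_subjects",
    "rank_combos",
    "load_fixture_table",
    "load_all_fixtures",
    "parse_combination_label",
]

CHROMOPHORES = ("HbO", "HbR")

_FIXTURE_FILES = {
    (2, "HbO"): "table_2feat_hbo.tsv",
    (2, "HbR"): "table_2feat_hbr.tsv",
    (3, "HbO"): "table_3feat_hbo.tsv",
    (3, "HbR"): "table_3feat_hbr.tsv",
}


@dataclass(frozen=True)
class ComboSpec:
    """One feature subset evaluated on one chromophore."""

    feature_names: tuple[str, ...]
    chromophore: str

    def __post_init__(self) -> None:
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError(f"duplicate feature names in {self.feature_names}")
        unknown = set(self.feature_names) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature name(s): {sorted(unknown)}")
        if self.chromophore not in CHROMOPHORES:
            raise ValueError(f"chromophore must be one of {CHROMOPHORES}")

    @property
    def size(self) -> int:
        return len(self.feature_names)

    @property
    def label(self) -> str:
        return "+".join(self.feature_names)

    def sort_key(self) -> tuple:
        # canonical: chromophore, size, then lexicographic in FEATURE_NAMES order
        idx = [FEATURE_NAMES.index(f) for f in self.feature_names]
        return (CHROMOPHORES.index(self.chromophore), self.size, tuple(idx))


@dataclass
class ComboResult:
    combo: ComboSpec
    per_subject_accuracy: dict[int, float]  # percent

    @property
    def mean_accuracy(self) -> float:
        return average_across_subjects(list(self.per_subject_accuracy.values()))


@dataclass
class PermutationResult:
    observed_diff: float  # mean paired accuracy difference, percentage points
    p_value: float
    n_permutations: int


def enumerate_combos(
    features: tuple[str, ...] = FEATURE_NAMES,
    sizes: tuple[int, ...] = (2, 3),
    chromophores: tuple[str, ...] = CHROMOPHORES,
) -> list[ComboSpec]:
    """All size-2/size-3 feature subsets per chromophore, in canonical order."""
    if len(set(features)) != len(features):
        raise ValueError("duplicate feature names")
    combos = [
        ComboSpec(feature_names=subset, chromophore=chrom)
        for chrom in chromophores
        for size in sizes
        for subset in itertools.combinations(features, size)
    ]
    return sorted(combos, key=ComboSpec.sort_key)


def score_all(
    features_df: pd.DataFrame,
    combos: list[ComboSpec],
    cvspec: CVSpec | None = None,
    ridge: float = 1e-8,
) -> list[ComboResult]:
    """Cross-validated accuracy of every combination, per subject.

    ``features_df`` is a (rescaled) epoch × feature table with ``subject``,
    ``chromophore`` and ``label`` provenance columns, as produced by
    :func:`nirscombo.features.feature_table`.
    """
    cvspec = cvspec or CVSpec()
    subjects = sorted(features_df["subject"].unique())
    results = []
    # pre-split per (subject, chromophore) once
    groups = {
        key: g for key, g in features_df.groupby(["subject", "chromophore"], sort=True)
    }
    for combo in combos:
        per_subject = {}
        for s in subjects:
            key = (s, combo.chromophore)
            if key not in groups:
                raise ValueError(f"missing features for subject {s}, {combo.chromophore}")
            g = groups[key]
            X = g[list(combo.feature_names)].to_numpy()
            y = (g["label"] == "task").to_numpy().astype(int)
            per_subject[s] = cross_validate(X, y, cvspec, ridge=ridge).mean_accuracy
        results.append(ComboResult(combo=combo, per_subject_accuracy=per_subject))
    return results


def compute_study_features(
    recordings,
    filter_spec=None,
    detrend_order: int | None = 1,
    ext=None,
    rescale: bool = True,
    on_degenerate: str = "error",
    drop_initial_rest: bool = True,
) -> pd.DataFrame:
    """Full per-study feature table: MBLL inversion → filtering → epochs → features.

    Returns one rescaled epoch × feature row table covering every subject and
    both chromophores, ready for :func:`score_all`.  The leading baseline rest
    block is dropped by default so task and rest classes are balanced (one
    rest epoch per task epoch).
    """
    from .features import epochize, feature_table, rescale_minmax
    from .mbll import mbll_invert
    from .preprocess import apply_filters

    frames = []
    for rec in recordings:
        hemo = mbll_invert(rec.od, ext)
        hemo = apply_filters(hemo, filter_spec, detrend_order)
        epochs = epochize(hemo, rec.labels, subject_id=rec.subject_id,
                          drop_initial_rest=drop_initial_rest)
        frames.append(feature_table(epochs, on_degenerate=on_degenerate))
    df = pd.concat(frames, ignore_index=True)
    if rescale:
        df, _ = rescale_minmax(df)
    return df


def permutation_test(a, b) -> PermutationResult:
    """Exact one-sided paired sign-flip test that ``a`` outperforms ``b``.

    Enumerates all 2ⁿ sign assignments of the paired differences; p is the
    proportion whose mean is ≥ the observed mean difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length (paired by subject)")
    n = a.size
    if n < 1:
        raise ValueError("need at least 1 pair")
    if n > 20:
        raise ValueError("exact enumeration limited to 20 pairs (2^n assignments)")
    d = a - b
    observed = d.mean()
    # all 2^n sign patterns as a (+1/-1) matrix from the binary expansion
    codes = np.arange(2**n, dtype=np.uint32)
    bits = (codes[:, None] >> np.arange(n)[None, :]) & 1
    signs = 1.0 - 2.0 * bits
    means = signs @ d / n
    p = float(np.mean(means >= observed - 1e-12))
    return PermutationResult(observed_diff=float(observed), p_value=p, n_permutations=2**n)


def holm_adjust(p_values: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjustment of a family of p-values (monotone, capped at 1).

    Optional honest-reporting mode; the default protocol reports raw p-values.
    """
    if not p_values:
        raise ValueError("no p-values to adjust")
    items = sorted(p_values.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted = {}
    running = 0.0
    for i, (name, p) in enumerate(items):
        running = max(running, (m - i) * p)
        adjusted[name] = min(1.0, running)
    return adjusted


def average_across_subjects(values) -> float:
    """Arithmetic mean of per-subject accuracies (cross-subject average, %)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no subject values to average")
    return float(values.mean())


def rank_combos(results: list[ComboResult]) -> list[ComboResult]:
    """Descending by mean accuracy; ties broken by canonical combo order."""
    if not results:
        raise ValueError("no results to rank")
    return sorted(results, key=lambda r: (-r.mean_accuracy, r.combo.sort_key()))


# ---------------------------------------------------------------------------
# Published-table fixture
# ---------------------------------------------------------------------------

def parse_combination_label(label: str) -> tuple[str, ...]:
    """Map a printed row name like 'Mean, Peak, and Slope' to canonical names."""
    cleaned = label.replace(",", " ").replace(" and ", " ").lower()
    names = tuple(sorted(cleaned.split(), key=FEATURE_NAMES.index))
    unknown = set(names) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unparseable combination label {label!r}")
    return names


def _read_fixture(name: str) -> str:
    ref = resources.files("nirscombo.data").joinpath(name)
    return ref.read_text()


def load_fixture_table(size: int, chromophore: str, verify: bool = True) -> pd.DataFrame:
    """Published per-subject accuracy table as a DataFrame indexed by combo tuple.

    Columns S1..S7 hold percent accuracies; the checksum of the shipped file
    is verified against the packaged manifest before parsing.
    """
    fname = _FIXTURE_FILES[(size, chromophore)]
    text = _read_fixture(fname)
    if verify:
        manifest = json.loads(_read_fixture("checksums.json"))
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != manifest[fname]:
            raise ValueError(f"fixture checksum mismatch for {fname}")
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t")
    df["features"] = df["combination"].map(parse_combination_label)
    return df.set_index("features")


def load_all_fixtures(verify: bool = True) -> dict[tuple[int, str], pd.DataFrame]:
    return {key: load_fixture_table(*key, verify=verify) for key in _FIXTURE_FILES}


def fixture_results(size: int, chromophore: str) -> list[ComboResult]:
    """Published table rows as ComboResult objects (subjects numbered 1..7)."""
    df = load_fixture_table(size, chromophore)
    subject_cols = [c for c in df.columns if c.startswith("S")]
    results = []
    for features, row in df.iterrows():
        combo = ComboSpec(feature_names=tuple(features), chromophore=chromophore)
        accs = {i + 1: float(row[c]) for i, c in enumerate(subject_cols)}
        results.append(ComboResult(combo=combo, per_subject_accuracy=accs))
    return results
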