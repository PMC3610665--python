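"""Scoring and diagnostics for phasing and imputation.

Switch errors follow the standard convention: only sites that are
heterozygous in the truth *and* genotype-concordant in the inference are
scored, and an error is a flip of the phase orientation between consecutive
scored sites.  A wholesale swap of the two haplotypes is not an error.

Genotype-sharing runs quantify why lock-in happens: *double* sharing
(identical genotypes) is where two individuals can feed each other arbitrary
phase; *single* sharing (no opposing homozygotes) is the weaker condition
copy-model phasing needs to work at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (MISSING, ConfigurationError, GenotypeMatrix, InputError)

RUN_KINDS = ("double", "single")


@dataclass
class SwitchErrorReport:
    """Switch errors of one individual against its true phase.

    ``per_marker`` flags the marker of the right-hand member of each
    disagreeing pair of scored sites (the localization convention used by
    the per-marker error map).  ``skipped_sites`` counts truth-het sites
    excluded because the inferred genotype disagreed with the truth there.
    """

    switch_count: int
    per_marker: np.ndarray  # (M,) bool
    skipped_sites: int
    n_scored_sites: int


@dataclass(frozen=True)
class SharingRun:
    """A maximal genotype-sharing run between two individuals, half-open."""

    pair: tuple[int, int]
    start: int
    end: int
    kind: str

    @property
    def length(self) -> int:
        return self.end - self.start


def switch_errors(true_pair: np.ndarray, inferred_pair: np.ndarray,
                  scoreable: np.ndarray | None = None) -> SwitchErrorReport:
    """Count phase switches of one inferred haplotype pair against truth.

    ``scoreable`` optionally restricts scoring to a boolean subset of
    markers — typically the markers actually typed in the study data, since
    the phase of markers missing in every individual is unconstrained by the
    data and scoring it only adds noise.
    """
    t = np.asarray(true_pair, dtype=np.int8)
    f = np.asarray(inferred_pair, dtype=np.int8)
    if t.shape != f.shape or t.ndim != 2 or t.shape[0] != 2:
        raise InputError("expected two (2, M) haplotype pairs of equal length")
    m = t.shape[1]
    het = t[0] != t[1]
    if scoreable is not None:
        scoreable = np.asarray(scoreable, dtype=bool)
        if scoreable.shape != (m,):
            raise InputError("scoreable mask must have one entry per marker")
        het = het & scoreable
    concordant = (t[0] + t[1]) == (f[0] + f[1])
    scored = np.nonzero(het & concordant)[0]
    skipped = int(np.count_nonzero(het) - len(scored))
    per_marker = np.zeros(m, dtype=bool)
    if len(scored) < 2:
        return SwitchErrorReport(0, per_marker, skipped, len(scored))
    agree = t[0, scored] == f[0, scored]
    flips = agree[1:] != agree[:-1]
    per_marker[scored[1:][flips]] = True
    return SwitchErrorReport(int(flips.sum()), per_marker, skipped, len(scored))


def cohort_switch_errors(true_haplotypes: np.ndarray,
                         inferred_haplotypes: np.ndarray,
                         individuals: np.ndarray | None = None,
                         scoreable: np.ndarray | None = None
                         ) -> list[SwitchErrorReport]:
    """Per-individual reports; ``individuals`` restricts scoring (e.g. to the
    original parents, keeping augmented scenarios comparable) and
    ``scoreable`` restricts the markers (e.g. to the typed, unmasked ones)."""
    t = np.asarray(true_haplotypes)
    f = np.asarray(inferred_haplotypes)
    if t.shape != f.shape:
        raise InputError("truth and inference haplotype arrays differ in shape")
    if individuals is None:
        individuals = np.arange(t.shape[0])
    return [switch_errors(t[i], f[i], scoreable) for i in individuals]


def total_switch_errors(reports: list[SwitchErrorReport]) -> int:
    return int(sum(r.switch_count for r in reports))


def imputed_allele_errors(truth_dosage: np.ndarray, imputed) -> int:
    """Incorrectly imputed alleles over all masked genotypes.

    Each masked genotype contributes |true dosage - imputed dosage|
    (0, 1 or 2 wrong alleles).  ``imputed`` is an
    :class:`~mirrorphase.impute.ImputationResult` or a bare (N, n_masked)
    dosage array paired with the truth restricted to the mask.
    """
    truth_dosage = np.asarray(truth_dosage)
    if hasattr(imputed, "imputed_dosage"):
        calls = imputed.imputed_dosage
        truth_at_mask = truth_dosage[:, imputed.mask]
    else:
        calls = np.asarray(imputed)
        truth_at_mask = truth_dosage
    if truth_at_mask.shape != calls.shape:
        raise InputError("truth and imputed dosages misaligned")
    valid = truth_at_mask != MISSING
    diff = np.abs(truth_at_mask.astype(np.int64) - calls.astype(np.int64))
    return int(np.minimum(diff, 2)[valid].sum())


def _sharing_condition(gA: np.ndarray, gB: np.ndarray, kind: str,
                       missing_matches: bool) -> np.ndarray:
    if kind not in RUN_KINDS:
        raise InputError(f"unknown run kind {kind!r}; expected one of {RUN_KINDS}")
    gA = np.asarray(gA, dtype=np.int64)
    gB = np.asarray(gB, dtype=np.int64)
    if gA.shape != gB.shape:
        raise InputError("dosage vectors differ in length")
    miss = (gA == MISSING) | (gB == MISSING)
    if kind == "double":
        cond = gA == gB
    else:
        cond = np.abs(gA - gB) <= 1  # no opposing homozygotes
    cond = np.where(miss, missing_matches, cond)
    return cond.astype(bool)


def sharing_runs(gA: np.ndarray, gB: np.ndarray, kind: str = "double",
                 pair: tuple[int, int] = (0, 1),
                 missing_matches: bool = True) -> list[SharingRun]:
    """Maximal runs where the sharing condition holds at every marker."""
    cond = _sharing_condition(gA, gB, kind, missing_matches)
    padded = np.concatenate([[False], cond, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    ends = np.nonzero(~padded[1:] & padded[:-1])[0]
    return [SharingRun(pair, int(s), int(e), kind) for s, e in zip(starts, ends)]


def _run_length_at_marker(cond: np.ndarray) -> np.ndarray:
    """Length of the condition run containing each marker (0 where false)."""
    out = np.zeros(len(cond), dtype=np.int64)
    padded = np.concatenate([[False], cond, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    ends = np.nonzero(~padded[1:] & padded[:-1])[0]
    for s, e in zip(starts, ends):
        out[s:e] = e - s
    return out


def best_match_stats(genotypes: GenotypeMatrix | np.ndarray, kind: str = "double",
                     missing_matches: bool = True) -> tuple[pd.DataFrame, dict]:
    """Best sharing-run length per individual and marker, aggregated.

    For each individual and marker, the best match is the longest kind-run
    containing that marker against any other individual.  Returns a
    per-individual table (mean and max over markers) and cohort aggregates,
    including the single longest run over all pairs.
    """
    d = genotypes.dosage if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    n, m = d.shape
    if n < 2:
        raise ConfigurationError("best-match statistics need at least 2 individuals")
    best = np.zeros((n, m), dtype=np.int64)
    longest = 0
    for i in range(n):
        for j in range(i + 1, n):
            cond = _sharing_condition(d[i], d[j], kind, missing_matches)
            lengths = _run_length_at_marker(cond)
            np.maximum(best[i], lengths, out=best[i])
            np.maximum(best[j], lengths, out=best[j])
            longest = max(longest, int(lengths.max(initial=0)))
    table = pd.DataFrame({
        "individual": np.arange(n),
        "mean_best_match": best.mean(axis=1),
        "max_best_match": best.max(axis=1),
    })
    cohort = {
        "mean_best_match": float(best.mean()),
        "max_best_match": int(best.max()),
        "longest_run": longest,
        "kind": kind,
    }
    return table, cohort


def per_marker_error_map(reports: dict[str, list[SwitchErrorReport]]) -> pd.DataFrame:
    """Per-marker switch-error rate (fraction of individuals) per method."""
    cols = {}
    m = None
    for method, reps in reports.items():
        if not reps:
            raise InputError(f"no reports for method {method!r}")
        stack = np.stack([r.per_marker for r in reps])
        if m is None:
            m = stack.shape[1]
        elif stack.shape[1] != m:
            raise InputError("reports disagree on marker count")
        cols[method] = stack.mean(axis=0)
    df = pd.DataFrame(cols)
    df.index.name = "marker"
    return df


def longest_above_median_run(rates: np.ndarray,
                             threshold: float | None = None) -> int:
    """Longest run of markers with error rate strictly above a threshold.

    The summary statistic for 'contiguous block' structure in the per-marker
    error map: locked-in regions produce long above-threshold runs, well-mixed
    chains produce scattered errors and short ones.  The default threshold is
    the median of ``rates`` itself; when comparing methods use
    :func:`error_map_block_lengths`, which puts all methods on one scale.
    """
    rates = np.asarray(rates, dtype=float)
    med = float(np.median(rates)) if threshold is None else threshold
    cond = rates > med
    if not cond.any():
        return 0
    return int(_run_length_at_marker(cond).max())


def error_map_block_lengths(error_map: pd.DataFrame,
                            markers: np.ndarray | None = None) -> dict[str, int]:
    """Longest above-threshold error-block length per method, shared scale.

    The threshold is the median of the pooled per-marker rates of *all*
    methods (a per-method median would be degenerate for a method with
    mostly error-free markers).  ``markers`` optionally restricts to a
    boolean subset — pass the typed markers when every second marker was
    masked, otherwise zero-rate masked markers break every run.
    """
    sub = error_map if markers is None else error_map.loc[np.asarray(markers, bool)]
    pooled = float(np.median(sub.to_numpy().ravel()))
    return {method: longest_above_median_run(sub[method].to_numpy(), pooled)
            for method in sub.columns}


def plot_error_map(df: pd.DataFrame, path: str) -> None:
    """Optional heat-strip rendering of a per-marker error-rate table."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ConfigurationError(
            "matplotlib is required for plotting (install mirrorphase[plot])"
        ) from exc
    fig, ax = plt.subplots(figsize=(10, 0.6 * len(df.columns) + 1))
    ax.imshow(df.to_numpy().T, aspect="auto", interpolation="nearest",
              cmap="Reds")
    ax.set_yticks(range(len(df.columns)), df.columns)
    ax.set_xlabel("marker")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def crossval_flip_rate(genotypes: GenotypeMatrix, config, k_subsets: int = 2,
                       holdout_fraction: float = 0.2, window: int = 50,
                       seed: int | None = None) -> pd.DataFrame:
    """Phase random subsets of the cohort and count flips between runs.

    Each of ``k_subsets`` runs omits a random ``holdout_fraction`` of
    individuals.  For every pair of runs and every individual phased in both,
    switch disagreements (one run scored against the other as truth) are
    binned into windows of ``window`` markers.  High-flip windows flag
    regions whose phase rests on too few informative individuals — the
    chain-mixing diagnostic usable without any truth.
    """
    from .engine import run_phasing  # local import to avoid a cycle

    if k_subsets < 2:
        raise ConfigurationError("cross-validation needs at least 2 subsets")
    if not 0 < holdout_fraction <= 0.5:
        raise ConfigurationError("holdout_fraction must lie in (0, 0.5]")
    n, m = genotypes.dosage.shape
    n_hold = max(1, int(round(holdout_fraction * n)))
    if n - n_hold < 2:
        raise ConfigurationError("cohort too small for the requested holdout")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    subsets, results = [], []
    from dataclasses import replace as _replace
    for s in range(k_subsets):
        held = rng.choice(n, size=n_hold, replace=False)
        keep = np.setdiff1d(np.arange(n), held)
        sub = GenotypeMatrix(dosage=genotypes.dosage[keep],
                             mask=genotypes.mask,
                             sample_ids=[genotypes.sample_ids[i] for i in keep])
        res = run_phasing(sub, config=_replace(config, seed=config.seed + 1000 * (s + 1)))
        subsets.append(keep)
        results.append(res)
    edges = np.arange(0, m + window, window)
    rows = []
    for s in range(k_subsets):
        for t in range(s + 1, k_subsets):
            common, ia, ib = np.intersect1d(subsets[s], subsets[t],
                                            return_indices=True)
            for ind, a, b in zip(common, ia, ib):
                rep = switch_errors(results[s].haplotypes[a],
                                    results[t].haplotypes[b])
                flips_per_window, _ = np.histogram(
                    np.nonzero(rep.per_marker)[0], bins=edges)
                for w, count in enumerate(flips_per_window):
                    if edges[w] < m:
                        rows.append({"individual": int(ind),
                                     "subset_pair": f"{s}-{t}",
                                     "window_start": int(edges[w]),
                                     "window_end": int(min(edges[w + 1], m)),
                                     "flips": int(count)})
    return pd.DataFrame(rows)
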