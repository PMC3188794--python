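"""Expression-library statistics: bottleneck-vs-expression correlations,
per-codon fitness screening, and partial-correlation codon ranking.

A library is a set of synonymous variants of one protein, each with a
measured protein abundance (fluorescence), culture optical density (OD, the
fitness proxy), and optionally an mRNA folding-energy covariate.  Protein
abundance divided by OD gives the per-cell abundance.  The analyses:

* correlate the bottleneck's relative location and relative strength with
  per-cell abundance (Pearson and Spearman), over the whole library and
  within a proximal location band, optionally as first-order partial
  correlations controlling for folding energy;
* screen every sense codon's copy number against OD with a Bonferroni
  threshold of alpha / 61;
* rank the fitness-reducing codons by the minimum absolute partial
  correlation over all single-codon controls — the codons whose OD
  association no other single codon explains away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bottleneck import DEFAULT_WINDOW_N, find_bottleneck
from .codon_model import CODON_TO_AA, SENSE_CODONS, CodingSequence, CodonWeightTable

__all__ = [
    "DEFAULT_PROXIMAL_BAND",
    "DEFAULT_ALPHA",
    "BONFERRONI_DIVISOR",
    "LibraryRecord",
    "CorrelationResult",
    "CodonFitnessReport",
    "CodonRankReport",
    "LibraryAnalysis",
    "per_cell_abundance",
    "correlate",
    "partial_correlate",
    "analyze_bottleneck_vs_expression",
    "codon_count_matrix",
    "codon_fitness_scan",
    "rank_fitness_codons",
]

DEFAULT_PROXIMAL_BAND = (0.16, 0.28)
DEFAULT_ALPHA = 0.05
BONFERRONI_DIVISOR = 61


@dataclass(frozen=True)
class LibraryRecord:
    """One library variant: sequence plus its bulk measurements."""

    variant_id: str
    seq: CodingSequence
    protein_abundance: float
    od: float
    folding_energy: float | None = None  # kcal/mol; more negative = more stable

    def __post_init__(self) -> None:
        if not self.od > 0:
            raise ValueError(f"variant {self.variant_id!r}: OD must be > 0, got {self.od}")
        if self.protein_abundance < 0:
            raise ValueError(
                f"variant {self.variant_id!r}: negative protein abundance"
            )


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # pearson | spearman | partial_pearson | partial_spearman
    r: float
    p_value: float
    n_obs: int
    controlled_for: str | None = None
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined:
            if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
                raise ValueError(f"correlation out of range: {self.r}")
            if not 0.0 <= self.p_value <= 1.0:
                raise ValueError(f"p-value out of range: {self.p_value}")


def per_cell_abundance(record: LibraryRecord) -> float:
    """Protein abundance normalized by OD (bulk signal per unit population)."""
    return record.protein_abundance / record.od


def _undefined(method: str, n: int, controlled_for: str | None = None) -> CorrelationResult:
    return CorrelationResult(
        method=method, r=float("nan"), p_value=float("nan"),
        n_obs=n, controlled_for=controlled_for, undefined=True,
    )


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p-value.

    Zero variance in either variable yields an undefined-flagged result
    (mirroring constant codon counts) rather than an exception.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = xa.size
    if n < 3:
        raise ValueError(f"correlation requires >= 3 observations, got {n}")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("correlation inputs must be finite")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return _undefined(method, n)
    if method == "pearson":
        res = stats.pearsonr(xa, ya)
    elif method == "spearman":
        res = stats.spearmanr(xa, ya)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(method=method, r=float(res.statistic), p_value=float(res.pvalue), n_obs=n)


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def partial_correlate(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    method: str = "pearson",
    controlled_for: str = "z",
) -> CorrelationResult:
    """First-order partial correlation of x and y controlling for z.

    ``r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))`` with a
    two-sided t-test at n - 3 degrees of freedom.  The rank-based variant
    applies the same formula to average-rank-transformed data (a large-sample
    approximation).  Degenerate controls (|r_xz| = 1 or |r_yz| = 1) and
    zero-variance inputs return an undefined-flagged result.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    za = np.asarray(z, dtype=float)
    if not (xa.shape == ya.shape == za.shape) or xa.ndim != 1:
        raise ValueError("x, y, z must be 1-d vectors of equal length")
    n = xa.size
    if n < 4:
        raise ValueError(f"partial correlation requires >= 4 observations, got {n}")
    if method == "spearman":
        xa, ya, za = (stats.rankdata(v) for v in (xa, ya, za))
        label = "partial_spearman"
    elif method == "pearson":
        label = "partial_pearson"
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0 or np.ptp(za) == 0:
        return _undefined(label, n, controlled_for)
    r_xy = _pearson_r(xa, ya)
    r_xz = _pearson_r(xa, za)
    r_yz = _pearson_r(ya, za)
    denom_sq = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom_sq <= 1e-14:
        return _undefined(label, n, controlled_for)
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom_sq)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(method=label, r=r, p_value=p, n_obs=n, controlled_for=controlled_for)


@dataclass
class LibraryAnalysis:
    """Bottleneck-vs-expression report.

    ``variant_table`` holds one row per variant (bottleneck parameters,
    per-cell abundance, folding energy); ``correlations`` one row per
    (parameter, subset, method, control) combination.
    """

    variant_table: pd.DataFrame
    correlations: pd.DataFrame
    window_n: int
    location_band: tuple[float, float]
    n_band: int

    def get(
        self,
        parameter: str,
        method: str = "pearson",
        subset: str = "all",
        controlled: str | None = None,
    ) -> CorrelationResult:
        sel = self.correlations
        mask = (
            (sel["parameter"] == parameter)
            & (sel["subset"] == subset)
            & (sel["method"] == method)
            & (sel["controlled_for"].fillna("") == (controlled or ""))
        )
        rows = sel[mask]
        if len(rows) != 1:
            raise KeyError(
                f"no unique correlation for parameter={parameter}, subset={subset}, "
                f"method={method}, controlled={controlled}"
            )
        row = rows.iloc[0]
        base = method if controlled is None else f"partial_{method}"
        return CorrelationResult(
            method=base, r=float(row["r"]), p_value=float(row["p_value"]),
            n_obs=int(row["n_obs"]), controlled_for=controlled,
            undefined=bool(np.isnan(row["r"])),
        )


def analyze_bottleneck_vs_expression(
    library: Sequence[LibraryRecord],
    weights: CodonWeightTable,
    n: int = DEFAULT_WINDOW_N,
    location_band: tuple[float, float] | None = DEFAULT_PROXIMAL_BAND,
    normalize_od: bool = True,
    log_abundance: bool = False,
) -> LibraryAnalysis:
    """Correlate bottleneck parameters with per-cell protein abundance.

    Computes each variant's bottleneck (window ``n``), then Pearson and
    Spearman correlations of relative location and relative strength against
    per-cell abundance, over the whole library and over the ``location_band``
    subset (inclusive bounds).  When every record carries a folding energy,
    partial correlations controlling for it are added.  ``normalize_od=False``
    treats the recorded abundance as already per-cell (constant-OD designs);
    ``log_abundance`` correlates against log abundance instead (Spearman is
    unaffected).
    """
    if len(library) < 3:
        raise ValueError("library analysis requires >= 3 records")
    rows = []
    for rec in library:
        bn = find_bottleneck(rec.seq, weights, n=n)
        abundance = per_cell_abundance(rec) if normalize_od else rec.protein_abundance
        rows.append(
            dict(
                variant_id=rec.variant_id,
                length_l=rec.seq.length_l,
                location_k=bn.location_k,
                relative_location=bn.relative_location,
                relative_strength=bn.relative_strength,
                strength=bn.strength,
                per_cell_abundance=abundance,
                od=rec.od,
                folding_energy=rec.folding_energy,
            )
        )
    table = pd.DataFrame(rows)
    abund = table["per_cell_abundance"].to_numpy()
    if log_abundance:
        if (abund <= 0).any():
            raise ValueError("log_abundance requires strictly positive abundances")
        abund = np.log(abund)
    have_folding = all(rec.folding_energy is not None for rec in library)
    folding = table["folding_energy"].to_numpy(dtype=float) if have_folding else None

    lo, hi = location_band if location_band is not None else (None, None)
    band_mask = (
        (table["relative_location"] >= lo) & (table["relative_location"] <= hi)
        if location_band is not None
        else pd.Series(False, index=table.index)
    )
    n_band = int(band_mask.sum())

    out = []

    def _add(parameter: str, subset: str, mask: np.ndarray) -> None:
        x = table.loc[mask, parameter].to_numpy()
        y = abund[np.asarray(mask)]
        for method in ("pearson", "spearman"):
            res = correlate(x, y, method)
            out.append(
                dict(parameter=parameter, subset=subset, method=method,
                     controlled_for=None, r=res.r, p_value=res.p_value, n_obs=res.n_obs)
            )
            if folding is not None:
                pres = partial_correlate(
                    x, y, folding[np.asarray(mask)], method, controlled_for="folding_energy"
                )
                out.append(
                    dict(parameter=parameter, subset=subset, method=method,
                         controlled_for="folding_energy", r=pres.r,
                         p_value=pres.p_value, n_obs=pres.n_obs)
                )

    all_mask = np.ones(len(table), dtype=bool)
    for parameter in ("relative_location", "relative_strength"):
        _add(parameter, "all", all_mask)
    if location_band is not None:
        if n_band < 3:
            warnings.warn(
                f"location band {location_band} selects only {n_band} records; "
                "band analysis skipped", stacklevel=2,
            )
        else:
            for parameter in ("relative_location", "relative_strength"):
                _add(parameter, "band", band_mask.to_numpy())
    correlations = pd.DataFrame(out)
    return LibraryAnalysis(
        variant_table=table,
        correlations=correlations,
        window_n=n,
        location_band=location_band if location_band is not None else (np.nan, np.nan),
        n_band=n_band,
    )


def codon_count_matrix(library: Sequence[LibraryRecord]) -> pd.DataFrame:
    """Variants x 61 sense codons copy-number matrix (rows sum to length_l)."""
    idx = {c: i for i, c in enumerate(SENSE_CODONS)}
    mat = np.zeros((len(library), len(SENSE_CODONS)), dtype=int)
    for row, rec in enumerate(library):
        for codon in rec.seq.codons:
            mat[row, idx[codon]] += 1
    return pd.DataFrame(mat, index=[rec.variant_id for rec in library], columns=SENSE_CODONS)


@dataclass
class CodonFitnessReport:
    """Per-codon copy-number-vs-OD screen with Bonferroni classification.

    Classes: ``negative``/``positive`` when the Pearson p-value is below
    ``alpha_corrected``; ``constant`` when the codon's count is identical
    across all variants (no correlation defined); ``not_significant``
    otherwise.
    """

    table: pd.DataFrame
    alpha: float
    alpha_corrected: float

    @property
    def classes(self) -> dict[str, str]:
        return dict(zip(self.table["codon"], self.table["class"]))

    def codons_in_class(self, cls: str) -> list[str]:
        return list(self.table.loc[self.table["class"] == cls, "codon"])


def codon_fitness_scan(
    library: Sequence[LibraryRecord],
    alpha: float = DEFAULT_ALPHA,
    bonferroni_divisor: int = BONFERRONI_DIVISOR,
) -> CodonFitnessReport:
    """Correlate each sense codon's copy number against OD (fitness proxy)."""
    if len(library) < 3:
        raise ValueError("codon fitness scan requires >= 3 records")
    counts = codon_count_matrix(library)
    od = np.array([rec.od for rec in library], dtype=float)
    alpha_corrected = alpha / bonferroni_divisor
    rows = []
    for codon in SENSE_CODONS:
        vec = counts[codon].to_numpy(dtype=float)
        res = correlate(vec, od, "pearson")
        if res.undefined:
            cls, r, p = "constant", float("nan"), float("nan")
        else:
            r, p = res.r, res.p_value
            if p < alpha_corrected:
                cls = "negative" if r < 0 else "positive"
            else:
                cls = "not_significant"
        rows.append(
            dict(
                codon=codon,
                amino_acid=CODON_TO_AA[codon],
                min_count=int(vec.min()),
                max_count=int(vec.max()),
                mean_count=float(vec.mean()),
                r=r,
                p_value=p,
                **{"class": cls},
            )
        )
    return CodonFitnessReport(
        table=pd.DataFrame(rows), alpha=alpha, alpha_corrected=alpha_corrected
    )


@dataclass
class CodonRankReport:
    """Fitness-reducing codons ranked by min |partial r| over single controls.

    ``partial_matrix`` holds M(i, j) = partial r(count_i, OD | count_j) for the
    kept (negatively correlated) codons; ``table`` is sorted descending by
    ``min_abs_partial_r``, so the top rows are the codons whose OD association
    no single other codon explains away.  ``excluded_constant`` lists codons
    dropped before step 1 because their count never varies.
    """

    table: pd.DataFrame
    partial_matrix: pd.DataFrame
    excluded_constant: list[str] = field(default_factory=list)

    @property
    def ranked_codons(self) -> list[str]:
        return list(self.table["codon"])


def rank_fitness_codons(library: Sequence[LibraryRecord]) -> CodonRankReport:
    """Three-step partial-correlation ranking of fitness-reducing codons.

    1. Keep codons whose copy number correlates negatively with OD.
    2. Build M(i, j) = partial r(count_i, OD | count_j) for all ordered pairs.
    3. Rank by each codon's minimum |M(i, j)| over controls j, descending.

    A single surviving codon falls back to |raw r| (min over an empty control
    set); pairs whose count vectors are perfectly collinear with the control
    are skipped as undefined.
    """
    if len(library) < 5:
        raise ValueError("codon ranking requires >= 5 records")
    counts = codon_count_matrix(library)
    od = np.array([rec.od for rec in library], dtype=float)

    excluded = [c for c in SENSE_CODONS if counts[c].nunique() == 1]
    varying = [c for c in SENSE_CODONS if c not in excluded]
    raw = {c: correlate(counts[c].to_numpy(dtype=float), od, "pearson").r for c in varying}
    kept = [c for c in varying if raw[c] < 0]
    if not kept:
        raise ValueError("no codon correlates negatively with OD")

    m = pd.DataFrame(np.nan, index=kept, columns=kept)
    min_abs: dict[str, float] = {}
    argmin: dict[str, str | None] = {}
    for ci in kept:
        x = counts[ci].to_numpy(dtype=float)
        best_val, best_j = np.inf, None
        for cj in kept:
            if cj == ci:
                continue
            res = partial_correlate(
                x, od, counts[cj].to_numpy(dtype=float), "pearson", controlled_for=cj
            )
            if res.undefined:
                continue
            m.loc[ci, cj] = res.r
            if abs(res.r) < best_val:
                best_val, best_j = abs(res.r), cj
        if best_j is None:  # no valid controlling partner: fall back to |raw r|
            best_val = abs(raw[ci])
        min_abs[ci] = float(best_val)
        argmin[ci] = best_j
    table = pd.DataFrame(
        dict(
            codon=kept,
            raw_r=[raw[c] for c in kept],
            min_abs_partial_r=[min_abs[c] for c in kept],
            controlling_codon=[argmin[c] for c in kept],
        )
    ).sort_values(
        ["min_abs_partial_r", "codon"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return CodonRankReport(table=table, partial_matrix=m, excluded_constant=excluded)
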