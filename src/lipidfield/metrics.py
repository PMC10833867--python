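"""Design-evaluation statistics: sequence recovery, distribution divergence,
confusion matrices, and per-residue perplexity.

Metrics compare designed sequences against the natives they were designed
from, optionally stratified by membrane region (lipid / interface /
aqueous) or burial, so that the behavior of an energy function can be
examined separately in each environment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import AA20


@dataclass
class SequencePairSet:
    """Paired (native, designed) sequences with optional position labels.

    ``region_labels`` and ``burial_labels``, when given, are lists parallel
    to the pairs, one label string per position.
    """

    pairs: list[tuple[str, str]]
    region_labels: list[list[str]] | None = None
    burial_labels: list[list[str]] | None = None

    def __post_init__(self):
        for k, (nat, des) in enumerate(self.pairs):
            if len(nat) != len(des):
                raise ValueError(
                    f"pair {k}: native length {len(nat)} != designed {len(des)}"
                )
        for name in ("region_labels", "burial_labels"):
            labels = getattr(self, name)
            if labels is not None:
                if len(labels) != len(self.pairs):
                    raise ValueError(f"{name} must cover every pair")
                for k, lab in enumerate(labels):
                    if len(lab) != len(self.pairs[k][0]):
                        raise ValueError(
                            f"{name}[{k}] must cover every position"
                        )

    def positions(self, region: str | None = None, burial: str | None = None):
        """Yield (native aa, designed aa) over positions passing the filter."""
        for k, (nat, des) in enumerate(self.pairs):
            for j in range(len(nat)):
                if region is not None:
                    if self.region_labels is None:
                        raise ValueError("no region labels present")
                    if self.region_labels[k][j] != region:
                        continue
                if burial is not None:
                    if self.burial_labels is None:
                        raise ValueError("no burial labels present")
                    if self.burial_labels[k][j] != burial:
                        continue
                yield nat[j], des[j]


@dataclass
class ConfusionMatrix:
    """20×20 design-vs-native probability table p(designed = s | native = r).

    Rows are native residues, columns designed residues.  Rows whose native
    residue never occurs are NaN and listed in ``undefined_rows``.
    """

    table: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self):
        row_sums = self.table.sum(axis=1, skipna=False)
        defined = ~row_sums.isna()
        if not np.allclose(row_sums[defined], 1.0, atol=1e-9):
            raise ValueError("defined confusion rows must sum to 1")

    @property
    def undefined_rows(self) -> list[str]:
        return self.table.index[self.table.isna().all(axis=1)].tolist()

    def row(self, native_code: str) -> np.ndarray:
        return self.table.loc[native_code].to_numpy()


def sequence_recovery(pairs: SequencePairSet, region: str | None = None,
                      burial: str | None = None) -> float:
    """Fraction of filtered positions where the design kept the native
    residue."""
    matches = total = 0
    for nat, des in pairs.positions(region, burial):
        total += 1
        matches += nat == des
    if total == 0:
        raise ValueError("no positions pass the filter")
    return matches / total


def aa_distribution(sequences, region_labels=None,
                    region: str | None = None) -> np.ndarray:
    """Probability of each of the 20 canonical amino acids over all
    (optionally region-filtered) positions, ordered as AA20."""
    counts = dict.fromkeys(AA20, 0)
    total = 0
    for k, seq in enumerate(sequences):
        for j, aa in enumerate(seq):
            if region is not None and region_labels[k][j] != region:
                continue
            if aa in counts:
                counts[aa] += 1
                total += 1
    if total == 0:
        raise ValueError("no positions to count")
    return np.array([counts[a] / total for a in AA20])


def kl_divergence(p_des: np.ndarray, q_nat: np.ndarray,
                  log_base: str = "e"):
    """Kullback–Leibler divergence of the designed residue distribution
    from the native one, plus per-residue log-likelihood differences.

    Returns ``(D_KL, D_s, D)`` where D_s[s] = log(p_s/q_s) (NaN where either
    probability is zero, excluded from D with a warning) and D = Σ D_s over
    the defined entries.  A negative D_s marks an under-enriched residue
    type.  D_KL uses 0·log 0 = 0; if the designed distribution has support
    where the native one has none, D_KL is infinite (returned as ``inf``,
    with a warning).  ``log_base``: 'e' (default) or '2'.
    """
    p = np.asarray(p_des, dtype=float)
    q = np.asarray(q_nat, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share shape")
    for name, v in (("p_des", p), ("q_nat", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not normalized (sum = {v.sum():.8f})")
    log = np.log2 if log_base == "2" else np.log

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(q > 0, p / np.where(q > 0, q, 1.0), np.nan)
        d_s = np.where((p > 0) & (q > 0), log(np.where(ratio > 0, ratio, 1.0)),
                       np.nan)
        terms = np.where(p > 0, p * log(np.where(ratio > 0, ratio, 1.0)), 0.0)
    if np.any((p > 0) & (q == 0)):
        warnings.warn(
            "designed distribution has support where the native distribution "
            "is zero; D_KL is infinite",
            stacklevel=2,
        )
        d_kl = float("inf")
    else:
        d_kl = float(terms.sum())
    if np.isnan(d_s).any():
        warnings.warn(
            f"{int(np.isnan(d_s).sum())} residue types with zero probability "
            "excluded from D",
            stacklevel=2,
        )
    d = float(np.nansum(d_s))
    return d_kl, d_s, d


def design_confusion(pairs: SequencePairSet, region: str | None = None,
                     burial: str | None = None) -> ConfusionMatrix:
    """Count native→designed substitutions into the 20×20 confusion table."""
    counts = pd.DataFrame(0, index=list(AA20), columns=list(AA20), dtype=int)
    for nat, des in pairs.positions(region, burial):
        if nat in counts.index and des in counts.columns:
            counts.loc[nat, des] += 1
    row_tot = counts.sum(axis=1)
    table = counts.div(row_tot.replace(0, np.nan), axis=0)
    return ConfusionMatrix(table, counts)


def perplexity(row: np.ndarray) -> float:
    """Perplexity 2^H of one confusion row, H in bits (0·log₂0 = 0).

    Ranges from 1 (one-hot, fully confident) to 20 (uniform over all
    canonical residues).
    """
    p = np.asarray(row, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"row must be a probability vector (sum={p.sum():.8f})")
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return float(2.0**entropy)


def per_residue_perplexity(cm: ConfusionMatrix) -> dict[str, float]:
    """Perplexity of each defined confusion row, keyed by native residue."""
    out = {}
    for code in cm.table.index:
        row = cm.table.loc[code].to_numpy()
        if not np.isnan(row).any():
            out[code] = perplexity(row)
    return out


def metrics_report(pairs: SequencePairSet,
                   regions: tuple[str, ...] = ()) -> dict:
    """Bundle of all metrics, overall and per requested region."""
    natives = [nat for nat, _ in pairs.pairs]
    designs = [des for _, des in pairs.pairs]

    def block(region=None):
        q = aa_distribution(natives, pairs.region_labels, region)
        p = aa_distribution(designs, pairs.region_labels, region)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d_kl, d_s, d = kl_divergence(p, q)
        cm = design_confusion(pairs, region)
        return {
            "recovery": sequence_recovery(pairs, region),
            "d_kl": d_kl if np.isfinite(d_kl) else None,
            "d": d,
            "d_s": {a: (None if np.isnan(v) else float(v))
                    for a, v in zip(AA20, d_s)},
            "perplexity": per_residue_perplexity(cm),
        }

    report = {"overall": block()}
    for region in regions:
        report[region] = block(region)
    return report
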