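"""Haplotype frequency estimation by expectation-maximization.

Implements the classic multilocus EM for unphased genotypes
(Excoffier-Slatkin style): the E-step weights every phase configuration
compatible with a sample's genotype by the product of its two haplotype
frequencies (doubled for heterozygous configurations), and the M-step
updates each haplotype frequency to its expected share of the 2n
chromosomes.  Per-individual diplotype posteriors follow directly from
the fitted frequencies; individuals enter downstream diplotype and
phenotype tables only if their best configuration reaches a posterior
threshold (0.95 by default).

The public surface is a model/results pair:

>>> model = HaplotypeFrequencyModel(matrix)
>>> res = model.fit()
>>> res.frequencies          # pandas Series, haplotype string -> freq
>>> calls = res.call_diplotypes(threshold=0.95)
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .panel import VariantPanel

Hap = tuple[int, ...]

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 500
DEFAULT_THRESHOLD = 0.95
REPORT_FREQ_THRESHOLD = 0.01  # a haplotype counts as "identified" above this
DROP_FREQ_THRESHOLD = 1e-6    # frequencies below this are dropped from reports


class PhasingError(ValueError):
    pass


def enumerate_diplotypes(genotype: Sequence[int]) -> list[tuple[Hap, Hap]]:
    """All unordered haplotype pairs compatible with an unphased genotype.

    ``genotype`` is a dosage vector (0/1/2 per locus; missing not
    allowed).  For h heterozygous loci there are 2**(h-1) unordered
    configurations (one when h == 0); the first heterozygous locus is
    pinned to break the hapA/hapB ordering symmetry.  Pairs are returned
    with hapA <= hapB lexicographically.
    """
    g = [int(x) for x in genotype]
    if any(x == MISSING for x in g):
        raise PhasingError("cannot enumerate diplotypes with missing calls")
    het = [i for i, x in enumerate(g) if x == 1]
    base = [x // 2 for x in g]  # 0 for dosage 0/1, 1 for dosage 2
    if not het:
        hap = tuple(base)
        return [(hap, hap)]
    configs = []
    # first het locus fixed: ref on hapA, alt on hapB
    for bits in itertools.product((0, 1), repeat=len(het) - 1):
        a, b = base[:], base[:]
        a[het[0]], b[het[0]] = 0, 1
        for locus, bit in zip(het[1:], bits):
            a[locus], b[locus] = bit, 1 - bit
        pair = tuple(a), tuple(b)
        configs.append((min(pair), max(pair)))
    return configs


def _config_weights(configs: list[tuple[Hap, Hap]], freqs: dict[Hap, float]) -> np.ndarray:
    w = np.empty(len(configs))
    for k, (a, b) in enumerate(configs):
        fa, fb = freqs.get(a, 0.0), freqs.get(b, 0.0)
        w[k] = (2.0 if a != b else 1.0) * fa * fb
    return w


def diplotype_posteriors(
    genotype: Sequence[int], freqs: dict[Hap, float] | pd.Series, panel: Optional[VariantPanel] = None
) -> dict[tuple[Hap, Hap], float]:
    """Posterior probability of each compatible phase configuration.

    ``freqs`` maps haplotype tuples (or, with ``panel`` given, allele
    strings) to frequencies.  Raises PhasingError if the genotype is
    incompatible with every positive-frequency haplotype.
    """
    if isinstance(freqs, pd.Series):
        if panel is None:
            raise ValueError("panel required to interpret string-indexed frequencies")
        freqs = {_hap_from_str(s, panel): f for s, f in freqs.items()}
    configs = enumerate_diplotypes(genotype)
    w = _config_weights(configs, freqs)
    total = w.sum()
    if total <= 0:
        raise PhasingError("genotype incompatible with every positive-frequency haplotype")
    return {cfg: float(wk / total) for cfg, wk in zip(configs, w)}


def _hap_from_str(s: str, panel: VariantPanel) -> Hap:
    if len(s) != len(panel):
        raise ValueError(f"haplotype string {s!r} does not match panel size")
    out = []
    for base, snp in zip(s, panel):
        if base == snp.ref_allele:
            out.append(0)
        elif base == snp.alt_allele:
            out.append(1)
        else:
            raise ValueError(f"{snp.rsid}: {base!r} is neither ref nor alt")
    return tuple(out)


@dataclass
class DiplotypeCall:
    """Best phase configuration for one individual."""

    sample_id: str
    hap_a: Hap
    hap_b: Hap
    posterior: float
    included: bool
    ambiguous: bool = False  # argmax tied; broken lexicographically


class HaplotypeFrequencyModel:
    """EM model for haplotype frequencies from unphased genotypes.

    Samples with a missing call at any panel locus are excluded from the
    likelihood (and from diplotype calling); their count is reported on
    the results object.
    """

    def __init__(self, matrix: GenotypeMatrix, panel: Optional[VariantPanel] = None):
        self.matrix = matrix
        self.panel = panel if panel is not None else matrix.panel
        mask = matrix.complete_mask()
        self._complete_idx = np.nonzero(mask)[0]
        if len(self._complete_idx) == 0:
            raise PhasingError("no samples with complete calls at panel loci")
        self.n_excluded_missing = int((~mask).sum())
        # Candidate haplotype space: union of haplotypes compatible with
        # at least one complete sample (not all 2^L).
        self._sample_configs: list[list[tuple[Hap, Hap]]] = []
        haps: dict[Hap, int] = {}
        for i in self._complete_idx:
            configs = enumerate_diplotypes(matrix.dosages[i])
            self._sample_configs.append(configs)
            for a, b in configs:
                haps.setdefault(a, len(haps))
                haps.setdefault(b, len(haps))
        self.haplotypes: list[Hap] = list(haps)
        self._ia = [
            np.array([haps[a] for a, _ in cfgs], dtype=np.intp)
            for cfgs in self._sample_configs
        ]
        self._ib = [
            np.array([haps[b] for _, b in cfgs], dtype=np.intp)
            for cfgs in self._sample_configs
        ]
        self._mult = [
            np.array([2.0 if a != b else 1.0 for a, b in cfgs])
            for cfgs in self._sample_configs
        ]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, panel: VariantPanel) -> "HaplotypeFrequencyModel":
        """Build from a sample x rsid DataFrame of 'X/Y' call strings."""
        from .genotypes import _parse_call

        samples = [str(s) for s in df.index]
        dosages = np.full((len(df), len(panel)), MISSING, dtype=np.int8)
        for j, snp in enumerate(panel):
            if snp.rsid in df.columns:
                for i, call in enumerate(df[snp.rsid].fillna(".")):
                    dosages[i, j] = _parse_call(str(call), snp)
        return cls(GenotypeMatrix(samples, dosages, panel))

    def _loglik_and_expected(self, f: np.ndarray) -> tuple[float, np.ndarray]:
        """One EM sweep: log-likelihood at f and expected haplotype counts."""
        counts = np.zeros_like(f)
        loglik = 0.0
        for ia, ib, mult in zip(self._ia, self._ib, self._mult):
            w = mult * f[ia] * f[ib]
            total = w.sum()
            if total <= 0 or not np.isfinite(total):
                return -np.inf, counts
            loglik += np.log(total)
            post = w / total
            np.add.at(counts, ia, post)
            np.add.at(counts, ib, post)
        return loglik, counts

    def loglik(self, freqs: np.ndarray | dict[Hap, float]) -> float:
        """Observed-data log-likelihood at the given frequencies."""
        if isinstance(freqs, dict):
            f = np.array([freqs.get(h, 0.0) for h in self.haplotypes])
        else:
            f = np.asarray(freqs, dtype=float)
        return self._loglik_and_expected(f)[0]

    def _run_em(self, f0: np.ndarray, tol: float, max_iter: int):
        f = f0.copy()
        n2 = 2.0 * len(self._complete_idx)
        trace = []
        converged = False
        prev = -np.inf
        for _ in range(max_iter):
            ll, counts = self._loglik_and_expected(f)
            trace.append(ll)
            if ll == -np.inf:
                raise PhasingError("non-finite likelihood during EM")
            if np.isfinite(prev) and abs(ll - prev) < tol:
                converged = True
                break
            prev = ll
            f = counts / n2
        return f, trace, converged

    def fit(
        self,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        n_restarts: int = 0,
        seed: Optional[int] = None,
        restrict_to_included: bool = False,
        threshold: float = DEFAULT_THRESHOLD,
    ) -> "HaplotypeFrequencyResults":
        """Run EM to convergence; optionally with seeded random restarts.

        With ``restrict_to_included=True`` the frequencies are
        re-estimated on the subset of individuals whose best diplotype
        posterior reaches ``threshold`` under the all-samples fit.
        """
        K = len(self.haplotypes)
        starts = [np.full(K, 1.0 / K)]
        if n_restarts:
            rng = np.random.default_rng(seed)
            starts += [rng.dirichlet(np.ones(K)) for _ in range(n_restarts)]
        best = None
        for f0 in starts:
            f, trace, converged = self._run_em(f0, tol, max_iter)
            if best is None or trace[-1] > best[1][-1]:
                best = (f, trace, converged)
        f, trace, converged = best
        res = HaplotypeFrequencyResults(
            model=self,
            freq_array=f,
            loglik_trace=np.array(trace),
            converged=converged,
            n_samples_used=len(self._complete_idx),
            n_excluded_missing=self.n_excluded_missing,
        )
        if restrict_to_included:
            calls = res.call_diplotypes(threshold)
            keep = {c.sample_id for c in calls if c.included}
            idx = [i for i in self._complete_idx if self.matrix.sample_ids[i] in keep]
            if not idx:
                raise PhasingError("no individuals pass the posterior threshold")
            sub = GenotypeMatrix(
                [self.matrix.sample_ids[i] for i in idx],
                self.matrix.dosages[idx],
                self.panel,
            )
            return HaplotypeFrequencyModel(sub, self.panel).fit(
                tol=tol, max_iter=max_iter, n_restarts=n_restarts, seed=seed
            )
        return res


@dataclass
class HaplotypeFrequencyResults:
    """Fitted haplotype frequencies plus convergence metadata."""

    model: HaplotypeFrequencyModel
    freq_array: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_samples_used: int
    n_excluded_missing: int

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def n_iter(self) -> int:
        return len(self.loglik_trace)

    @property
    def freqs(self) -> dict[Hap, float]:
        return {h: float(f) for h, f in zip(self.model.haplotypes, self.freq_array)}

    @property
    def frequencies(self) -> pd.Series:
        """Frequencies indexed by haplotype allele string, descending."""
        panel = self.model.panel
        s = pd.Series(
            {panel.hap_str(h): float(f) for h, f in zip(self.model.haplotypes, self.freq_array)},
            name="frequency",
        )
        s.index.name = "haplotype"
        return s.sort_values(ascending=False, kind="stable")

    def reported_haplotypes(self, threshold: float = REPORT_FREQ_THRESHOLD) -> pd.Series:
        """Haplotypes 'identified' in the cohort: frequency > threshold."""
        f = self.frequencies
        return f[f > threshold]

    def diplotype_posteriors(self, sample_id: str) -> dict[tuple[Hap, Hap], float]:
        i = self.model.matrix.sample_ids.index(sample_id)
        return diplotype_posteriors(self.model.matrix.dosages[i], self.freqs)

    def call_diplotypes(self, threshold: float = DEFAULT_THRESHOLD) -> list[DiplotypeCall]:
        """Best diplotype per complete sample; included iff posterior >= threshold."""
        panel = self.model.panel
        freqs = self.freqs
        calls = []
        for i, configs in zip(self.model._complete_idx, self.model._sample_configs):
            sid = self.model.matrix.sample_ids[i]
            w = _config_weights(configs, freqs)
            total = w.sum()
            if total <= 0:
                raise PhasingError(f"sample {sid}: unresolvable under fitted frequencies")
            post = w / total
            top = post.max()
            ties = [configs[k] for k in np.nonzero(np.isclose(post, top, rtol=0, atol=1e-12))[0]]
            # deterministic tie-break: lexicographic on allele strings
            best = min(ties, key=lambda p: (panel.hap_str(p[0]), panel.hap_str(p[1])))
            calls.append(
                DiplotypeCall(
                    sample_id=sid,
                    hap_a=best[0],
                    hap_b=best[1],
                    posterior=float(top),
                    included=bool(top >= threshold),
                    ambiguous=len(ties) > 1,
                )
            )
        return calls

    def calls_frame(self, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
        panel = self.model.panel
        rows = [
            (c.sample_id, panel.hap_str(c.hap_a), panel.hap_str(c.hap_b),
             c.posterior, c.included, c.ambiguous)
            for c in self.call_diplotypes(threshold)
        ]
        return pd.DataFrame(
            rows, columns=["sample", "hap_a", "hap_b", "posterior", "included", "ambiguous"]
        )

    def summary(self) -> str:
        lines = [
            "Haplotype frequency estimate (EM)",
            f"  samples used: {self.n_samples_used}"
            f" (excluded for missing calls: {self.n_excluded_missing})",
            f"  iterations: {self.n_iter}  converged: {self.converged}",
            f"  log-likelihood: {self.loglik:.6f}",
            "",
            "  haplotype  frequency",
        ]
        for hap, f in self.frequencies.items():
            if f >= DROP_FREQ_THRESHOLD:
                lines.append(f"  {hap:<10} {f:.4f}")
        return "\n".join(lines)


def em_haplotype_frequencies(
    matrix: GenotypeMatrix,
    panel: Optional[VariantPanel] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    **kwargs,
) -> HaplotypeFrequencyResults:
    """Functional wrapper over HaplotypeFrequencyModel(...).fit(...)."""
    return HaplotypeFrequencyModel(matrix, panel).fit(tol=tol, max_iter=max_iter, **kwargs)


def call_diplotypes(
    matrix: GenotypeMatrix,
    freqs: HaplotypeFrequencyResults,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[DiplotypeCall]:
    """Call best diplotypes for ``matrix`` under fitted frequencies."""
    if freqs.model.matrix is matrix:
        return freqs.call_diplotypes(threshold)
    model = HaplotypeFrequencyModel(matrix, freqs.model.panel)
    res = HaplotypeFrequencyResults(
        model=model,
        freq_array=np.array([freqs.freqs.get(h, 0.0) for h in model.haplotypes]),
        loglik_trace=freqs.loglik_trace,
        converged=freqs.converged,
        n_samples_used=freqs.n_samples_used,
        n_excluded_missing=freqs.n_excluded_missing,
    )
    return res.call_diplotypes(threshold)
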