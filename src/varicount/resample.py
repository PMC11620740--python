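"""Bootstrap sample-size analysis for the variance estimator.

Because the estimator consumes a *dispersion*, its own sampling
variability depends sharply on how many animals contribute to that
dispersion.  Resampling an observed pool of marker fractions with
replacement at a range of cohort sizes, re-estimating the precursor
number on each resample, and summarising the spread of those estimates
as a relative error (SD of the bootstrap estimates divided by their
mean) quantifies how quickly estimate variability shrinks with cohort
size.  On the data behind this method the curve flattens around five
samples per group, which is where the pipeline's default minimum group
size comes from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import FrequencySeries

__all__ = ["SampleSizeCurve", "sample_size_curve"]


@dataclass(frozen=True)
class SampleSizeCurve:
    """Relative error of the estimate as a function of cohort size.

    ``relative_error[i]`` is SD(bootstrap n_hat)/mean(bootstrap n_hat)
    at cohort size ``sizes[i]``; ``degenerate_fraction[i]`` is the share
    of resamples skipped because all drawn values coincided (sigma = 0)
    or the mean was 0/1.  Sizes where that share exceeds one half are
    flagged unreliable.
    """

    sizes: tuple[int, ...]
    relative_error: tuple[float, ...]
    degenerate_fraction: tuple[float, ...]
    n_boot: int
    seed: int | None
    flags: tuple[str, ...] = ()


def sample_size_curve(
    series: FrequencySeries,
    sizes: "list[int]",
    n_boot: int = 1000,
    seed: int | None = None,
) -> SampleSizeCurve:
    """Bootstrap the estimate at each cohort size in ``sizes``.

    For each size ``s``: draw ``n_boot`` resamples of size ``s`` with
    replacement from the pooled fractions, estimate the precursor number
    on each non-degenerate resample, and report
    SD(n_hat)/mean(n_hat).  Degenerate resamples (all values equal, or
    mean at 0/1) are skipped and counted, not imputed.
    """
    sizes = [int(s) for s in sizes]
    if any(s < 2 for s in sizes):
        raise ValueError("every resample size must be >= 2")
    if sorted(set(sizes)) != sizes:
        raise ValueError("sizes must be strictly increasing")
    if len(series) <= max(sizes):
        raise ValueError("series must be larger than the largest resample size")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    rng = np.random.default_rng(seed)
    values = series.values
    rel_errors, degen_fracs, flags = [], [], []
    for s in sizes:
        draws = values[rng.integers(0, values.size, size=(n_boot, s))]
        means = draws.mean(axis=1)
        sds = draws.std(axis=1, ddof=1)
        valid = (sds > 0) & (means > 0) & (means < 1)
        degen = 1.0 - valid.mean()
        degen_fracs.append(float(degen))
        if degen > 0.5:
            flags.append(f"unreliable-size-{s}")
        n_hats = means[valid] * (1.0 - means[valid]) / sds[valid] ** 2
        if n_hats.size < 2:
            rel_errors.append(0.0)
            flags.append(f"degenerate-size-{s}")
            continue
        rel_errors.append(float(n_hats.std(ddof=1) / n_hats.mean()))
    if n_boot == 1:
        flags.append("degenerate-nboot")
    return SampleSizeCurve(
        sizes=tuple(sizes),
        relative_error=tuple(rel_errors),
        degenerate_fraction=tuple(degen_fracs),
        n_boot=n_boot,
        seed=seed,
        flags=tuple(flags),
    )
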