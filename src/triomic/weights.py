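"""Gene observation weights from RPKM rate modelling.

Lowly sequenced genes carry noisier fold-change estimates.  The weighting
scheme models per-gene RPKM with an exponential distribution (the
maximum-likelihood rate is the reciprocal mean; with an inverse link the
fitted linear predictor *is* the rate), scores each gene by how far its mean
RPKM reaches into the upper tail of an exponential law with the
transcriptome-wide pooled rate, and converts the scores to weights via the
cumulative hazard of their empirical distribution:

    score_g  = 1 - exp(-lambda_pool * mean_g)          in [0, 1)
    weight_g = -ln(1 - Fhat(score_g)),  Fhat = rank/(G+1)

The cumulative hazard grows slowly through the bulk of the score
distribution and steeply for the best-represented genes; the top-ranked
gene's weight is exactly ln(G+1), which is also the default clip.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def gene_weights(
    rpkm: pd.DataFrame, floor: float = 0.01, clip: float | None = None
) -> pd.DataFrame:
    """Per-gene rate, significance score and cumulative-hazard weight.

    Parameters
    ----------
    rpkm
        gene x sample nonnegative expression matrix.
    floor
        additive floor applied before averaging, matching the fold-change
        kernel.
    clip
        maximum weight; defaults to ``ln(G+1)``, the value attained by the
        top-ranked gene under the rank/(G+1) empirical CDF.

    Returns
    -------
    DataFrame with columns ``rate`` (per-gene exponential MLE rate),
    ``score`` and ``weight``, indexed by gene.
    """
    if rpkm.shape[0] < 2:
        raise ValueError("need at least 2 genes for the empirical score CDF")
    if (rpkm.values < 0).any():
        raise ValueError("negative RPKM")
    mean = rpkm.mean(axis=1) + floor
    rate = 1.0 / mean
    pooled_rate = 1.0 / float(mean.mean())
    # upper-tail probability of the gene mean under Exp(pooled_rate)
    tail = np.exp(-pooled_rate * mean)
    score = 1.0 - tail
    g = len(score)
    ranks = score.rank(method="average")
    fhat = ranks / (g + 1)
    weight = -np.log1p(-fhat)
    cap = np.log(g + 1) if clip is None else float(clip)
    weight = weight.clip(upper=cap)
    return pd.DataFrame({"rate": rate, "score": score, "weight": weight})
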