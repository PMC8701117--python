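"""Direction-concordance of a discovery DM set in an independent twin cohort.

For each cell type of the replication cohort the paired delta/t analysis is
recomputed at the discovery probes, and each probe is tallied as concordant
when the sign of its replication mean delta matches the discovery sign.
Significant concordance additionally requires a replication paired-t
p < 0.05. A zero replication delta counts as discordant (conservative).
Global concordance is assessed with an exact binomial sign test against a
0.5 chance rate.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix
from .methylation import paired_deltas, paired_ttest

log = logging.getLogger(__name__)

__all__ = ["concordance"]


def concordance(
    discovery_dm: pd.DataFrame,
    replication: Mapping[str, BetaMatrix],
    sig_p: float = 0.05,
) -> pd.DataFrame:
    """Per-cell-type concordance summary of discovery DM probes.

    ``discovery_dm`` must be indexed by probe id with a ``mean_delta``
    column. ``replication`` maps cell type to its replication
    :class:`BetaMatrix` (>= 2 discordant pairs each). Discovery probes absent
    from a replication matrix are logged and excluded from that cell type.
    """
    rows = []
    for cell_type, beta in replication.items():
        if beta.n_pairs < 2:
            raise ValueError(f"{cell_type}: replication needs >= 2 pairs")
        present = discovery_dm.index.intersection(beta.probe_ids)
        missing = len(discovery_dm.index) - len(present)
        if missing:
            log.info("%s: %d discovery probes absent from replication array", cell_type, missing)
        if len(present) == 0:
            raise ValueError(f"{cell_type}: no overlapping probes")
        sub = beta.subset_probes(present)
        tests = paired_ttest(paired_deltas(sub))
        disc_sign = np.sign(discovery_dm.loc[present, "mean_delta"].to_numpy(dtype=float))
        rep_sign = np.sign(tests["mean_delta"].to_numpy(dtype=float))
        conc = (rep_sign == disc_sign) & (rep_sign != 0)
        sig = tests["p"].to_numpy(dtype=float) < sig_p
        n = int(len(present))
        n_conc = int(conc.sum())
        sign_test = stats.binomtest(n_conc, n, 0.5, alternative="two-sided")
        rows.append(
            {
                "cell_type": cell_type,
                "n_tested": n,
                "n_concordant": n_conc,
                "n_discordant": n - n_conc,
                "n_sig_concordant": int((conc & sig).sum()),
                "n_sig_discordant": int((~conc & sig).sum()),
                "concordance_fraction": n_conc / n,
                "sign_test_p": sign_test.pvalue,
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")
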