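"""Independent brute-force rule enumerator used as the mining oracle.

Enumerates every ordered rule by explicit iteration over virus combinations
and state assignments (no Apriori pruning, no shared code with the package's
vectorized miner) and scores it by direct row counting.
"""

from itertools import combinations, product

import numpy as np


def brute_force_rules(values01, virus_ids, max_lhs, min_support, min_confidence):
    """All candidate rules as {(lhs_items, rhs_item): (support, conf, lift)}.

    ``values01`` is the (n x V) 0/1 array over the mined strains; lhs_items is
    a frozenset of (virus_id, state) and rhs_item a (virus_id, state) tuple.
    """
    vals = np.asarray(values01)
    n, V = vals.shape
    sat = {}  # item -> boolean row mask
    for j, vid in enumerate(virus_ids):
        sat[(vid, True)] = vals[:, j] == 1
        sat[(vid, False)] = vals[:, j] == 0

    out = {}
    for k in range(1, max_lhs + 1):
        for lhs_viruses in combinations(virus_ids, k):
            for lhs_states in product((True, False), repeat=k):
                lhs = tuple(zip(lhs_viruses, lhs_states))
                lhs_mask = np.ones(n, dtype=bool)
                for item in lhs:
                    lhs_mask &= sat[item]
                cnt_lhs = int(lhs_mask.sum())
                for rhs_virus in virus_ids:
                    if rhs_virus in lhs_viruses:
                        continue
                    for rhs_state in (True, False):
                        rhs = (rhs_virus, rhs_state)
                        cnt_full = int((lhs_mask & sat[rhs]).sum())
                        support = cnt_full / n
                        if not support >= min_support:
                            continue
                        conf = cnt_full / cnt_lhs if cnt_lhs > 0 else 0.0
                        if not conf >= min_confidence:
                            continue
                        cnt_rhs = int(sat[rhs].sum())
                        lift = (cnt_full * n / (cnt_lhs * cnt_rhs)
                                if cnt_lhs > 0 and cnt_rhs > 0 else 0.0)
                        out[(frozenset(lhs), rhs)] = (support, conf, lift)
    return out


def frame_to_oracle_dict(rules_frame):
    """Key the package's rules frame the same way for comparison."""
    return {
        (frozenset(row["lhs_items"]), (row["rhs_virus"], row["rhs_state"])):
        (row["support"], row["confidence"], row["lift"])
        for _, row in rules_frame.iterrows()
    }
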