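#!/usr/bin/env python
"""Neighbor-Joining phylogeny with site-bootstrap support.

Builds the NJ tree from the normalized divergence matrix and annotates the
two internal edges with 1,000-replicate bootstrap support; writes
results/nj_tree.nwk.
"""

from pathlib import Path

import probmsc as pm

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = Path(__file__).resolve().parent.parent / "scratch" / "sim"


def main() -> None:
    filtered = pm.read_site_table(SIM / "study.sites.filtered.tsv")
    tree = pm.bootstrap_support(filtered, replicates=1000, seed=1)
    (ROOT / "nj_tree.nwk").write_text(tree.newick() + "\n")
    print(tree.newick())
    ok = tree.splits() == {frozenset({"S", "F"}), frozenset({"S", "F", "O"})}
    print("species topology (((S,F),(A,M)),O) recovered:", ok)


if __name__ == "__main__":
    main()
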