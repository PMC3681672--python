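"""Irreversible parsimony on the worked four-biopsy matrix.

Biopsy 1 carries SGAs {a,b}, biopsy 2 {a,b,c}, biopsy 3 {c,d} and
biopsy 4 {d}.  With reversals forbidden and an all-normal LUCA outgroup,
the best topology pairs (1,2) against (3,4) with five gains — character
c must arise twice (convergent evolution).
"""

import numpy as np

from sgaclock.matrix import Character, SgaMatrix
from sgaclock.parsimony import branch_lengths, camin_sokal_score, search_max_parsimony

chars = [Character("chr1", 10_000_000 * j, 10_000_000 * j + 5_000_000, "")
         for j in range(4)]
data = np.array([[1, 1, 0, 0],
                 [1, 1, 1, 0],
                 [0, 0, 1, 1],
                 [0, 0, 0, 1]], dtype=np.uint8)
matrix = SgaMatrix(["1", "2", "3", "4"], chars, data)

trees, score = search_max_parsimony(matrix)
print(f"optimal score {score} over {len(trees)} co-optimal topologies")
best = camin_sokal_score(trees[0], matrix)
for j, char in enumerate(matrix.characters):
    gains = [";".join(b) for b in best.placements[j]]
    print(f"character {'abcd'[j]} ({char.label}): gains on {gains}")
counts = branch_lengths(best, "count")
mbs = branch_lengths(best, "Mb", matrix.sizes_bp)
print("branch lengths (events | Mb):")
for bid in counts:
    print(f"  {'|'.join(bid)}: {counts[bid]:.0f} | {mbs[bid]:.0f}")
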