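"""Assemble read islands — transcribed regions independent of any model.

An island is a maximal interval where every base has read depth >= 3
and the interval is at least 100 bp long.  Islands flag expression in
regions where no model was accepted.
"""

import numpy as np

from genesift import Contig, Genome, assemble_read_islands
from genesift.evidence import CoverageTrack

depth = np.zeros(2000)
depth[100:350] = 12    # strong 250-bp block        -> island
depth[500:580] = 40    # only 80 bp, too short      -> no island
depth[700:1400] = 3    # exactly at the depth floor -> island
depth[1500:1800] = 2   # below the depth floor      -> no island

genome = Genome([Contig("chr1", "A" * 2000)])
islands = assemble_read_islands(CoverageTrack({"chr1": depth}))

for contig, start, end in islands:
    print(f"island {contig}:{start}-{end} ({end - start + 1} bp)")

# Two islands: 101-350 and 701-1400.  The 80-bp block fails the length
# floor and the depth-2 block fails the depth floor, however long it is.
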