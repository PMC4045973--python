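"""Paint linkage groups with ancestral gene blocks and compare the
fragmentation of a block between the two genomes.

Uses the shipped table of block intervals (A. thaliana gene-ID spans)
to reproduce the classic pattern: a block complete in the B genome but
split across two A-genome linkage groups.
"""

import importlib.resources

import pandas as pd

from allomap.blocks import (block_table_to_definitions, call_blocks,
                            fragmentation_compare)
from allomap.io import read_block_table

path = importlib.resources.files("allomap.data") / "published_blocks.tsv"
defs = block_table_to_definitions(read_block_table(str(path)))

cols = ["marker_id", "lg_id", "position_cM", "at_id", "subgenome_class"]
markers_A = pd.DataFrame([
    ("mk1", "A10", 0.0, "At1g02500", "LF"),
    ("mk2", "A10", 4.0, "At1g06000", "LF"),
    ("mk3", "A6", 0.0, "At1g08000", "LF"),
    ("mk4", "A6", 5.0, "At1g18000", "LF"),
], columns=cols)
markers_B = pd.DataFrame([
    ("mk5", "B4", 0.0, "At1g03000", "LF"),
    ("mk6", "B4", 3.0, "At1g07000", "LF"),
    ("mk7", "B4", 6.0, "At1g12000", "LF"),
    ("mk8", "B4", 9.0, "At1g19000", "LF"),
], columns=cols)

calls_A = call_blocks(markers_A, "A", defs)
calls_B = call_blocks(markers_B, "B", defs)
for c in calls_A + calls_B:
    print(f"{c.genome} genome {c.lg_id}: block {c.block_id}({c.subgenome_class}) "
          f"{c.at_span[0]}-{c.at_span[1]} [{len(c.supporting_markers)} markers]")

rec = fragmentation_compare("A", "LF", calls_A, calls_B)
print(f"block A(LF): {rec.classification}")
# split_in_A: the block is one unit on LG B4 but divided between LGs A10
# and A6 — the two genomes fractured this ancestral block differently.
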