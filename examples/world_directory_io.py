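"""Round-trip a world through the plain-text directory layout.

The same layout serves synthetic worlds and real-data adapters, so the
pipeline consumes both identically; the `bflows` command line operates on
these directories (`bflows run --world DIR --out DIR`).
"""

import tempfile
from pathlib import Path

from bflows import duo_fixture, read_world, run_analysis, write_country_summary, write_world

world = duo_fixture()
with tempfile.TemporaryDirectory() as tmp:
    world_dir = Path(tmp) / "duo"
    write_world(world, world_dir)
    print("world directory:", *sorted(p.name for p in world_dir.iterdir()), "\n")

    mrio, extensions, proxies, pb = read_world(world_dir)
    res = run_analysis(mrio, extensions, proxies, pb)
    out = Path(tmp) / "summary.csv"
    write_country_summary(res, out)
    print(out.read_text())

print("Each row pairs one region and indicator with its footprints, boundary,")
print("transgressions, per-capita burden and the no-trade comparison.")
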