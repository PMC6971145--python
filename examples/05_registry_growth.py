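"""Grow a registry without ever renaming: the append-only contract.

Curates a subset of the standard haplotypes, saves the registry, then
re-curates with the full set against the saved registry. Previously issued
names are bit-identical; only additions appear.
"""

import tempfile
from pathlib import Path

from bfbl import Registry, curate, standard_fixture

fx = standard_fixture()
subset = {"B2", "B4", "B5"}

first = curate(
    [r for r in fx.records if r.haplotype in subset],
    [e for e in fx.evidence if e.seq_id.split("_")[0] in subset],
)
with tempfile.TemporaryDirectory() as tmp:
    first.registry.save(Path(tmp) / "v1")
    print(f"v1: {len(first.registry.entries)} names issued")

    registry = Registry.load(Path(tmp) / "v1")
    second = curate(fx.records, fx.evidence, registry=registry, null_slots=fx.null_slots)
    print(f"v2: {len(second.allocations)} new names, old names untouched:")
    for digest, entry in sorted(first.registry.entries.items()):
        assert second.registry.entries[digest].name == entry.name
        print(f"   {entry.name.render()} (stable)")
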