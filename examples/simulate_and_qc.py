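"""Simulate a polymerase synthesis pool with sequencing artifacts and QC it.

Builds a Taq-like pool (bimodal 80/400 nt lengths, GT/AT/poly-A/random
mixture), adds terminal adapters and 5% concatemers, then trims, flags and
filters. The report counts removals per rule; retained reads passed the
median Q >= 13 and length > 65 nt cutoffs and carry no internal adapter.
"""

import json

from doodlekit.qc import qc_pipeline
from doodlekit.reads import AdapterSet
from doodlekit.simulate import DEFAULT_ADAPTER, add_sequencing_artifacts, simulate_pool, taq65_pool_spec

pool = simulate_pool(taq65_pool_spec(n_reads=1000, seed=42, target_median_q=16))
with_artifacts = add_sequencing_artifacts(pool, concatemer_rate=0.05, seed=43)

filtered, report = qc_pipeline(with_artifacts, AdapterSet((DEFAULT_ADAPTER,)))
print("filter report:", json.dumps(report.to_dict(), indent=2))
print(f"retained {len(filtered)} reads; median length "
      f"{sorted(len(r) for r in filtered)[len(filtered) // 2]} nt")
# trimmed_5p/_3p count adapter cuts; concatemers are reads with an internal
# adapter (two ligated fragments read as one); fail_length/fail_quality are
# the library-fragment and accuracy filters.
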