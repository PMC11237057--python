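"""Box-Jenkins condition-deviation descriptors on a tiny worked dataset.

Each raw descriptor D becomes three features D_tn, D_st, D_at: the
deviation of the compound's value from the mean over *actives* measured
under the same target / standard type / assay type.  A compound that
looks exactly like a typical active under its own condition has
deviation 0.
"""

import numpy as np

from mtqsar.box_jenkins import condition_averages, deviation_transform
from mtqsar.synthetic import worked_fixture

records, raw = worked_fixture()
print("raw descriptors:")
print(raw)

averages = condition_averages(raw, records)
print("\nmean of each descriptor over ACE actives:")
print(averages.lookup("tn", "ACE").round(3).to_dict())

features = deviation_transform(raw, averages, records)
print(f"\ndeviation matrix: {features.shape[0]} x {features.shape[1]} (3x raw width)")
print(features.round(3).iloc[:, :4])

# the deviation columns are centred on the actives that defined them:
actives_ace = [i for i, r in zip(features.index, records) if r.is_active and r.target.value == "ACE"]
col_means = features.loc[actives_ace, [c for c in features.columns if c.endswith("_tn")]].mean()
print("\nmean deviation over ACE actives (exactly zero):", np.round(col_means.to_numpy(), 12))
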