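"""Shape-first, size-second retrieval from the clover-head feature database.

Loads the seven packaged clover-head parameter rows into a database, then
queries it three ways: an exact stored shape, a shape within the 0.005
gamma tolerance (a 0.7 degree head-angle change), and an oversized main
vein that triggers size adjustment.
"""

from bionicvein import ImplantType, ParameterSet
from bionicvein.feature_db import FeatureDatabase, add_record, retrieve
from bionicvein.templates import load_parameter_table, packaged_table_path

rows = load_parameter_table(packaged_table_path(1), ImplantType.CLOVER_HEAD)
db = FeatureDatabase()
for row in rows:
    add_record(db, ImplantType.CLOVER_HEAD, row)
print(f"database: {len(db)} clover-head records (19 vein points each)")


def show(tag, res):
    print(f"{tag}: {res.status.value}, record {res.record.record_id}, "
          f"delta1={res.delta1:+.4f} delta2={res.delta2:+.4f} delta3={res.delta3:+.4f}")


# 1. the exact parameters of stored row 2 retrieve themselves
show("row-2 self-query     ", retrieve(db, ImplantType.CLOVER_HEAD, rows[1]))

# 2. a 0.7 deg branch-angle change: |delta gamma| = 0.0039 <= 0.005, still a
#    shape match ("within one degree")
near = dict(rows[1].values)
near["alpha4"] += 0.7
show("0.7 deg angle change ", retrieve(
    db, ImplantType.CLOVER_HEAD, ParameterSet(ImplantType.CLOVER_HEAD, near)))

# 3. main vein 30% longer: shape matches, |delta3| > 0.1, so the stored
#    feature's main vein is adjusted and the result stored as a new record
big = dict(rows[1].values)
big["h3"] *= 1.3
big["h4"] *= 1.3
show("oversized main vein  ", retrieve(
    db, ImplantType.CLOVER_HEAD, ParameterSet(ImplantType.CLOVER_HEAD, big)))
print(f"database now holds {len(db)} records (adjusted features are inserted)")
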