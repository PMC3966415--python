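"""Generate a synthetic claims database and look at its shape.

The generator emulates a national-insurance outpatient extract for a
breast-cancer population: most visits carry the index diagnosis, ~7% of
patients use Chinese herbal medicine (CHM), and each CHM prescription
averages ~6.5 items with the core Hedyotis diffusa + Scutellaria barbata
pair implanted at its published joint prevalence.
"""
from herbnet import default_config, generate
from herbnet.io import write_claims

config = default_config(seed=1)
db = generate(config)
write_claims(db, "scratch/claims")

n_chm = db.visits["flags"].str.contains("CHM").sum()
sizes = db.prescriptions.groupby("visit_id").size()
print(f"patients:            {len(db.patients):>8}")
print(f"visits:              {len(db.visits):>8}")
print(f"CHM (TCM) visits:    {n_chm:>8}")
print(f"catalog items:       {len(db.catalog):>8}")
print(f"mean items per CHM prescription: {sizes.mean():.2f}")
# Expect ~6.5 items per prescription and a few percent CHM visits — the
# structure the downstream cohort extraction and rule mining assume.
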