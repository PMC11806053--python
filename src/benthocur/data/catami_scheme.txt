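# Minimal CATAMI v1.4 core scheme fixture (user-extensible).
# One " > "-delimited path per line; optional tab-separated provenance tag.
# Parents are listed before children; branch roots are implicit.
Substrate > Consolidated (hard)
Substrate > Consolidated (hard) > Rock
Substrate > Consolidated (hard) > Boulders
Substrate > Consolidated (hard) > Cobbles
Substrate > Unconsolidated (soft)
Substrate > Unconsolidated (soft) > Sand / mud (<1mm)
Substrate > Unconsolidated (soft) > Sand / mud (<1mm) > Mud / silt (<64um)
Substrate > Unconsolidated (soft) > Sand / mud (<1mm) > Sand (no shell fragments)
Substrate > Unconsolidated (soft) > Pebble / gravel
Biota > Worms
Biota > Worms > Polychaetes
Biota > Worms > Polychaetes > Tube worms
Biota > Cnidaria
Biota > Cnidaria > Corals
Biota > Cnidaria > Corals > Stony corals
Biota > Cnidaria > Corals > Stony corals > Solitary
Biota > Cnidaria > Corals > Stony corals > Solitary > Free living
Biota > Macroalgae
Biota > Seagrasses
Biota > Sponges
Biota > Echinoderms
Biota > Echinoderms > Sea stars
Biota > Molluscs
Biota > Molluscs > Bivalves
Bedforms > None
Bedforms > Ripples
Relief > Flat
Relief > Low (<1m)
Anthropogenic > Debris (trash)	extension
Anthropogenic > Cables	extension
Biota > Macroalgae > Encrusting
Biota > Macroalgae > Filamentous / filiform
Biota > Sponges > Massive forms
Biota > Sponges > Cup-likes
Biota > Cnidaria > Hydroids
Biota > Cnidaria > True anemones
Biota > Echinoderms > Sea urchins
Biota > Echinoderms > Sea cucumbers
Biota > Molluscs > Gastropods
Biota > Ascidians
Biota > Bryozoa
Biota > Crustacea
Biota > Fishes
Bedforms > Waves
Relief > Moderate (1-3m)
Relief > High (>3m)
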