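dataset,original_label,branch,path,qualifiers,bleached,dead,colour,aphia_id
*,Cobble,Substrate,Substrate > Consolidated (hard) > Cobbles,,,,,
*,Mud and tube worms,Substrate,Substrate > Unconsolidated (soft) > Sand / mud (<1mm) > Mud / silt (<64um),,,,,
*,Mud and tube worms,Biota,Biota > Worms > Polychaetes > Tube worms,,,,,883
*,Hard Coral:Non hermatypic:Free living (Fungia etc),Biota,Biota > Cnidaria > Corals > Stony corals > Solitary > Free living,,,,,1363
*,Pocillopora sp.,Biota,Biota > Cnidaria > Corals > Stony corals,,,,,206938
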