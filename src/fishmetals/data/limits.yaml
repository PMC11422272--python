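# Maximum permissible limits for metals in fish muscle (human consumption).
# All limits are expressed on a wet-weight basis; display_sigfigs reproduces
# the precision each converted dry-weight value is conventionally quoted at.
limits:
  - {jurisdiction: Mexico-NOM, metal: Cd, limit: 0.5, basis: ww, display_sigfigs: 2}
  - {jurisdiction: EU,         metal: Cd, limit: 0.3, basis: ww, display_sigfigs: 2}
  - {jurisdiction: US-FDA,     metal: Cd, limit: 0.5, basis: ww, display_sigfigs: 2}
  - {jurisdiction: US-FDA,     metal: Pb, limit: 1.3, basis: ww, display_sigfigs: 3}
  - {jurisdiction: Australia,  metal: Cu, limit: 10,  basis: ww, display_sigfigs: 2}
  - {jurisdiction: Australia,  metal: Zn, limit: 150, basis: ww, display_sigfigs: 1}
  - {jurisdiction: India,      metal: Cu, limit: 10,  basis: ww, display_sigfigs: 2}
  - {jurisdiction: India,      metal: Zn, limit: 50,  basis: ww, display_sigfigs: 2}
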