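# Decomposition of nucleotide chemical components into binding modules.
#
# Each component lists its module fragments in architecture order
# (nucleobase / carbohydrate / phosphate).  Atom names follow PDB
# chemical-component conventions; hydrogens are never listed.  Bridging
# ester oxygens (ribose O5' and inter-phosphate O3A/O3B/O3 bridges) are
# assigned to the phosphate they esterify, so every heavy atom belongs
# to exactly one fragment.  A fragment marked `branch: true` hangs off
# the linear architecture (the 2'-phosphate of NADP).

components:
  AMP:
    fragments:
      - {type: nucleobase, subtype: adenine,
         atoms: [N9, C8, N7, C5, C6, N6, N1, C2, N3, C4]}
      - {type: carbohydrate, subtype: ribose_closed,
         atoms: ["C1'", "C2'", "O2'", "C3'", "O3'", "C4'", "O4'", "C5'"]}
      - {type: phosphate, subtype: phosphate,
         atoms: ["O5'", P, OP1, OP2, OP3]}
  ADP:
    fragments:
      - {type: nucleobase, subtype: adenine,
         atoms: [N9, C8, N7, C5, C6, N6, N1, C2, N3, C4]}
      - {type: carbohydrate, subtype: ribose_closed,
         atoms: ["C1'", "C2'", "O2'", "C3'", "O3'", "C4'", "O4'", "C5'"]}
      - {type: phosphate, subtype: phosphate,
         atoms: ["O5'", PA, O1A, O2A, O3A]}
      - {type: phosphate, subtype: phosphate,
         atoms: [PB, O1B, O2B, O3B]}
  ATP:
    fragments:
      - {type: nucleobase, subtype: adenine,
         atoms: [N9, C8, N7, C5, C6, N6, N1, C2, N3, C4]}
      - {type: carbohydrate, subtype: ribose_closed,
         atoms: ["C1'", "C2'", "O2'", "C3'", "O3'", "C4'", "O4'", "C5'"]}
      - {type: phosphate, subtype: phosphate,
         atoms: ["O5'", PA, O1A, O2A, O3A]}
      - {type: phosphate, subtype: phosphate,
         atoms: [PB, O1B, O2B, O3B]}
      - {type: phosphate, subtype: phosphate,
         atoms: [PG, O1G, O2G, O3G]}
  ANP:
    fragments:
      - {type: nucleobase, subtype: adenine,
         atoms: [N9, C8, N7, C5, C6, N6, N1, C2, N3, C4]}
      - {type: carbohydrate, subtype: ribose_closed,
         atoms: ["C1'", "C2'", "O2'", "C3'", "O3'", "C4'", "O4'", "C5'"]}
      - {type: phosphate, subtype: phosphate,
         atoms: ["O5'", PA, O1A, O2A, O3A]}
      - {type: phosphate, subtype: phosphate,
         atoms: [PB, O1B, O2B, N3B]}
      - {type: phosphate, subtype: phosphate,
         atoms: [PG, O1G, O2G, O3G]}
  GDP:
    fragments:
      - {type: nucleobase, subtype: guanine,
         atoms: [N9, C8, N7, C5, C6, O6, N1, C2, N2, N3, C4]}
      - {type: carbohydrate, subtype: ribose_closed,
         atoms: ["C1'", "C2'", "O2'", "C3'", "O3'", "C4'", "O4'", "C5'"]}
      - {type: phosphate, subtype: phosphate,
         atoms: ["O5'", PA, O1A, O2A, O3A]}
      - {type: phosphate, subtype: phosphate,
         atoms: [PB, O1B, O2B, O3B]}
  GTP:
    fragments:
      - {type: nucleobase, subtype: guanine,
         atoms: [N9, C8, N7, C5, C6, O6, N1, C2, N2, N3, C4]}
      - {type: carbohydrate, subtype: ribose_closed,
         atoms: ["C1'", "C2'", "O2'", "C3'", "O3'", "C4'", "O4'", "C5'"]}
      - {type: phosphate, subtype: phosphate,
         atoms: ["O5'", PA, O1A, O2A, O3A]}
      - {type: phosphate, subtype: phosphate,
         atoms: [PB, O1B, O2B, O3B]}
      - {type: phosphate, subtype: phosphate,
         atoms: [PG, O1G, O2G, O3G]}
  GNP:
    fragments:
      - {type: nucleobase, subtype: guanine,
         atoms: [N9, C8, N7, C5, C6, O6, N1, C2, N2, N3, C4]}
      - {type: carbohydrate, subtype: ribose_closed,
         atoms: ["C1'", "C2'", "O2'", "C3'", "O3'", "C4'", "O4'", "C5'"]}
      - {type: phosphate, subtype: phosphate,
         atoms: ["O5'", PA, O1A, O2A, O3A]}
      - {type: phosphate, subtype: phosphate,
         atoms: [PB, O1B, O2B, N3B]}
      - {type: phosphate, subtype: phosphate,
         atoms: [PG, O1G, O2G, O3G]}
  FMN:
    fragments:
      - {type: nucleobase, subtype: flavin,
         atoms: [N1, C2, O2, N3, C4, O4, C4A, N5, C5A, C6, C7, C7M,
                 C8, C8M, C9, C9A, N10, C10]}
      - {type: carbohydrate, subtype: ribose_open,
         atoms: ["C1'", "C2'", "O2'", "C3'", "O3'", "C4'", "O4'", "C5'"]}
      - {type: phosphate, subtype: phosphate,
         atoms: ["O5'", P, O1P, O2P, O3P]}
  FAD:
    fragments:
      - {type: nucleobase, subtype: flavin,
         atoms: [N1, C2, O2, N3, C4, O4, C4X, N5, C5X, C6, C7, C7M,
                 C8, C8M, C9, C9A, N10, C10]}
      - {type: carbohydrate, subtype: ribose_open,
         atoms: ["C1'", "C2'", "O2'", "C3'", "O3'", "C4'", "O4'", "C5'"]}
      - {type: phosphate, subtype: phosphate,
         atoms: ["O5'", P, O1P, O2P, O3P]}
      - {type: phosphate, subtype: phosphate,
         atoms: [PA, O1A, O2A, O5B]}
      - {type: carbohydrate, subtype: ribose_closed,
         atoms: [C1B, C2B, O2B, C3B, O3B, C4B, O4B, C5B]}
      - {type: nucleobase, subtype: adenine,
         atoms: [N9A, C8A, N7A, C5A, C6A, N6A, N1A, C2A, N3A, C4A]}
  NAD:
    fragments:
      - {type: nucleobase, subtype: nicotinamide,
         atoms: [N1N, C2N, C3N, C7N, O7N, N7N, C4N, C5N, C6N]}
      - {type: carbohydrate, subtype: ribose_closed,
         atoms: [C1D, C2D, O2D, C3D, O3D, C4D, O4D, C5D]}
      - {type: phosphate, subtype: phosphate,
         atoms: [O5D, PN, O1N, O2N, O3]}
      - {type: phosphate, subtype: phosphate,
         atoms: [PA, O1A, O2A, O5B]}
      - {type: carbohydrate, subtype: ribose_closed,
         atoms: [C1B, C2B, O2B, C3B, O3B, C4B, O4B, C5B]}
      - {type: nucleobase, subtype: adenine,
         atoms: [N9A, C8A, N7A, C5A, C6A, N6A, N1A, C2A, N3A, C4A]}
  NAP:
    fragments:
      - {type: nucleobase, subtype: nicotinamide,
         atoms: [N1N, C2N, C3N, C7N, O7N, N7N, C4N, C5N, C6N]}
      - {type: carbohydrate, subtype: ribose_closed,
         atoms: [C1D, C2D, O2D, C3D, O3D, C4D, O4D, C5D]}
      - {type: phosphate, subtype: phosphate,
         atoms: [O5D, PN, O1N, O2N, O3]}
      - {type: phosphate, subtype: phosphate,
         atoms: [PA, O1A, O2A, O5B]}
      - {type: carbohydrate, subtype: ribose_closed,
         atoms: [C1B, C2B, O2B, C3B, O3B, C4B, O4B, C5B]}
      - {type: nucleobase, subtype: adenine,
         atoms: [N9A, C8A, N7A, C5A, C6A, N6A, N1A, C2A, N3A, C4A]}
      - {type: phosphate, subtype: phosphate, branch: true,
         atoms: [P2B, O1X, O2X, O3X]}
  # free (single-module) components
  ADE:
    fragments:
      - {type: nucleobase, subtype: adenine,
         atoms: [N9, C8, N7, C5, C6, N6, N1, C2, N3, C4]}
  RIB:
    fragments:
      - {type: carbohydrate, subtype: ribose_closed,
         atoms: ["C1'", "C2'", "O2'", "C3'", "O3'", "C4'", "O4'", "C5'"]}
  PO4:
    fragments:
      - {type: phosphate, subtype: phosphate,
         atoms: [P, O1, O2, O3, O4]}
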