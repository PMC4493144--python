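{
 "frame_length": 612,
 "provenance": {
  "source": "published character-based key for Mediterranean scombrid COI barcodes",
  "frame": "612-column trimmed barcode alignment, positions 1-based"
 },
 "clades": [
  {
   "name": "Thunnus spp.",
   "level": "genus",
   "parent": null,
   "species": [
    "Thunnus thynnus",
    "Thunnus alalunga",
    "Thunnus albacares",
    "Thunnus maccoyii",
    "Thunnus obesus",
    "Thunnus atlanticus"
   ],
   "cas": [
    {"pos": 327, "state": "A"},
    {"pos": 372, "state": "G"},
    {"pos": 525, "state": "T"},
    {"pos": 540, "state": "T"}
   ]
  },
  {
   "name": "Thunnus alalunga",
   "level": "species",
   "parent": "Thunnus spp.",
   "species": ["Thunnus alalunga"],
   "cas": [
    {"pos": 228, "state": "T"},
    {"pos": 273, "state": "G"},
    {"pos": 438, "state": "C"},
    {"pos": 495, "state": "T"},
    {"pos": 606, "state": "G"},
    {"pos": 609, "state": "T"}
   ]
  },
  {
   "name": "Thunnus thynnus",
   "level": "species",
   "parent": "Thunnus spp.",
   "species": ["Thunnus thynnus"],
   "cas": [
    {"pos": 231, "state": "T"}
   ]
  },
  {
   "name": "T. thynnus/T. albacares/T. maccoyii/T. obesus/T. atlanticus",
   "level": "residual-group",
   "parent": "Thunnus spp.",
   "species": [
    "Thunnus thynnus",
    "Thunnus albacares",
    "Thunnus maccoyii",
    "Thunnus obesus",
    "Thunnus atlanticus"
   ],
   "cas": [
    {"pos": 228, "state": "C"},
    {"pos": 273, "state": "A"},
    {"pos": 495, "state": "C"},
    {"pos": 606, "state": "A"},
    {"pos": 609, "state": "C"}
   ]
  },
  {
   "name": "Auxis spp.",
   "level": "genus",
   "parent": null,
   "species": ["Auxis rochei", "Auxis thazard"],
   "cas": [
    {"pos": 393, "state": "T", "compound_id": "auxis-triple"},
    {"pos": 453, "state": "T", "compound_id": "auxis-triple"},
    {"pos": 456, "state": "C", "compound_id": "auxis-triple"}
   ]
  },
  {
   "name": "Auxis rochei",
   "level": "species",
   "parent": "Auxis spp.",
   "species": ["Auxis rochei"],
   "cas": [
    {"pos": 225, "state": "T"},
    {"pos": 247, "state": "T"},
    {"pos": 315, "state": "C"},
    {"pos": 336, "state": "T"},
    {"pos": 348, "state": "C"},
    {"pos": 465, "state": "A"},
    {"pos": 468, "state": "A"},
    {"pos": 486, "state": "T"}
   ]
  },
  {
   "name": "Auxis thazard",
   "level": "species",
   "parent": "Auxis spp.",
   "species": ["Auxis thazard"],
   "cas": [
    {"pos": 225, "state": "C"},
    {"pos": 247, "state": "C"},
    {"pos": 315, "state": "T"},
    {"pos": 336, "state": "C"},
    {"pos": 348, "state": "T"},
    {"pos": 465, "state": "G"},
    {"pos": 468, "state": "G"},
    {"pos": 486, "state": "C"}
   ]
  },
  {
   "name": "Euthynnus alletteratus",
   "level": "species",
   "parent": null,
   "species": ["Euthynnus alletteratus"],
   "cas": [
    {"pos": 303, "state": "G"},
    {"pos": 312, "state": "A"},
    {"pos": 408, "state": "G"},
    {"pos": 426, "state": "G"},
    {"pos": 498, "state": "G"},
    {"pos": 553, "state": "T"}
   ]
  },
  {
   "name": "Scomber spp.",
   "level": "genus",
   "parent": null,
   "species": ["Scomber colias", "Scomber japonicus", "Scomber scombrus"],
   "cas": [
    {"pos": 81, "state": "T"},
    {"pos": 127, "state": "G"},
    {"pos": 210, "state": "A"},
    {"pos": 235, "state": "C"},
    {"pos": 249, "state": "G"},
    {"pos": 258, "state": "G"},
    {"pos": 260, "state": "C"},
    {"pos": 351, "state": "C"},
    {"pos": 393, "state": "C"},
    {"pos": 434, "state": "G"},
    {"pos": 519, "state": "T"}
   ]
  },
  {
   "name": "Scomber colias/japonicus",
   "level": "residual-group",
   "parent": "Scomber spp.",
   "species": ["Scomber colias", "Scomber japonicus"],
   "cas": [
    {"pos": 93, "state": "C"},
    {"pos": 192, "state": "T"},
    {"pos": 225, "state": "G"},
    {"pos": 240, "state": "G"},
    {"pos": 306, "state": "C"},
    {"pos": 312, "state": "G"},
    {"pos": 321, "state": "A"},
    {"pos": 342, "state": "T"},
    {"pos": 414, "state": "C"},
    {"pos": 423, "state": "A"},
    {"pos": 436, "state": "G"},
    {"pos": 438, "state": "A"},
    {"pos": 561, "state": "T"},
    {"pos": 612, "state": "C"}
   ]
  },
  {
   "name": "Scomber scombrus",
   "level": "species",
   "parent": "Scomber spp.",
   "species": ["Scomber scombrus"],
   "cas": [
    {"pos": 67, "state": "G"},
    {"pos": 72, "state": "T"},
    {"pos": 129, "state": "C"},
    {"pos": 240, "state": "A"},
    {"pos": 303, "state": "A"},
    {"pos": 306, "state": "A"},
    {"pos": 321, "state": "G"},
    {"pos": 507, "state": "G"},
    {"pos": 543, "state": "T"},
    {"pos": 546, "state": "T"}
   ]
  },
  {
   "name": "Sarda sarda",
   "level": "species",
   "parent": null,
   "species": ["Sarda sarda"],
   "cas": [
    {"pos": 216, "state": "T"},
    {"pos": 258, "state": "T"},
    {"pos": 264, "state": "C"},
    {"pos": 279, "state": "G"},
    {"pos": 543, "state": "G"},
    {"pos": 567, "state": "T"}
   ]
  },
  {
   "name": "Katsuwonus pelamis",
   "level": "species",
   "parent": null,
   "species": ["Katsuwonus pelamis"],
   "cas": [
    {"pos": 366, "state": "T"},
    {"pos": 378, "state": "T"},
    {"pos": 390, "state": "A"},
    {"pos": 501, "state": "G"},
    {"pos": 555, "state": "G"},
    {"pos": 582, "state": "T"}
   ]
  }
 ]
}
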