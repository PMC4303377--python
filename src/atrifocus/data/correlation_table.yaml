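# Default torso-quadrant -> atrial-quadrant correlation table with the
# anatomical regions contained in each atrial quadrant, for the two atrial
# orientations supported out of the box. position1 follows the textbook
# orientation of the atria in the thorax; position2 follows the orientation
# obtained directly from the segmented anatomy. Users may supply a
# patient-specific table with the same schema.
#
# Region abbreviations: RA right atrium, RAA right atrial appendage,
# PM pectinate muscles, CT crista terminalis, SAN sinoatrial node,
# SVC/IVC superior/inferior vena cava, AVR atrio-ventricular ring,
# AS atrial septum, BB Bachmann's bundle, LA left atrium, LAA left atrial
# appendage, RPV/LPV right/left pulmonary veins, RSPV/LSPV/RIPV/LIPV the
# individual pulmonary veins.
qt_to_qa:
  Qt1: Qa1
  Qt2: Qa2
  Qt3: Qa3
  Qt4: Qa4
  Qt5: Qa5
  Qt6: Qa6
  Qt7: Qa7
  Qt8: Qa8
variants:
  position1:
    Qa1:
      - Superior-anterior part of RA
      - right part of RAA
      - superior part of the PM
      - superior part CT
      - superior part of the SAN
      - anterior part of the SVC
    Qa2:
      - Left part of RAA
    Qa3:
      - Inferior-anterior part of the RA
      - inferior part of the PM
      - inferior anterior part of the CT
      - inferior part of the SAN
    Qa4:
      - inferior-anterior-left part of the RA
      - anterior part of the AVR
    Qa5:
      - RPV
      - superior-right part of LA
      - superior part of the AS
      - BB
      - posterior part of the SVC
    Qa6:
      - LPV
      - superior-left part of the LA
      - LAA
      - posterior part of the AVR
    Qa7:
      - inferior part of the AS
      - inferior-right part of the LA
      - inferior-posterior part of the CT
      - IVC
    Qa8:
      - inferior-left part of the LA
  position2:
    Qa1:
      - Superior-anterior part of RA
      - right part of RAA
      - SAN
      - PM
      - Superior part of CT
    Qa2:
      - Left part of RAA
    Qa3:
      - Inferior-anterior part of the RA
      - inferior anterior part of the CT
      - AVR
      - inferior-anterior part of IVC
    Qa4:
      - Anterior part of AVR
    Qa5:
      - RSPV
      - superior-right part of LA
      - BB
      - SVC
      - superior part of AS
    Qa6:
      - LSPV
      - superior-left part of LA
      - LAA
      - posterior part of AVR
    Qa7:
      - RIPV
      - inferior part of AS
      - inferior-right part of LA
      - inferior-posterior part of IVC
    Qa8:
      - LIPV
      - inferior-left part of LA
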