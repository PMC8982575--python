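# Reporter -> (laser, band-pass filter) detection-channel map for a
# five-laser FACSAria III class instrument, with commonly used antibody
# fluorophores of similar spectral characteristics mapped to the same
# channels. Lasers in nm; filters as center/width strings.
reporters:
  - name: Azurite
    channels:
      - {laser_nm: 355, laser_name: UV, filter: "450/40"}
      - {laser_nm: 405, laser_name: Violet, filter: "450/40"}
  - name: mTagBFP2
    channels:
      - {laser_nm: 405, laser_name: Violet, filter: "450/40"}
  - name: Ametrine
    channels:
      - {laser_nm: 405, laser_name: Violet, filter: "510/50"}
  - name: EGFP
    aliases: [GFP]
    channels:
      - {laser_nm: 488, laser_name: Blue, filter: "530/30"}
  - name: Venus
    channels:
      - {laser_nm: 488, laser_name: Blue, filter: "530/30"}
  - name: mOrange
    channels:
      - {laser_nm: 488, laser_name: Blue, filter: "582/15"}
      - {laser_nm: 561, laser_name: Yellow/Green, filter: "582/15"}
  - name: mCherry2
    channels:
      - {laser_nm: 561, laser_name: Yellow/Green, filter: "610/20"}
  - name: E2-Crimson
    channels:
      - {laser_nm: 633, laser_name: Red, filter: "660/20"}
fluorophores:
  - {name: Indo-1 hi, like: Azurite, lasers: [355]}
  - {name: Alexa Fluor 350, like: Azurite, lasers: [355]}
  - {name: Marina Blue, like: Azurite, lasers: [355]}
  - {name: Brilliant Violet 421, like: mTagBFP2}
  - {name: Pacific Blue, like: mTagBFP2}
  - {name: Alexa Fluor 405, like: mTagBFP2}
  - {name: Sytox Blue, like: mTagBFP2}
  - {name: Brilliant Violet 510, like: Ametrine}
  - {name: AmCyan, like: Ametrine}
  - {name: Krome Orange, like: Ametrine}
  - {name: FITC, like: EGFP}
  - {name: Alexa Fluor 488, like: EGFP}
  - {name: CFSE, like: EGFP}
  - {name: Sytox Green, like: EGFP}
  - {name: Dylight 488, like: EGFP}
  - {name: PE, like: mOrange}
  - {name: PI, like: mOrange}
  - {name: Alexa Fluor 555, like: mOrange}
  - {name: Dylight 549, like: mOrange}
  - {name: PE/Texas Red, like: mCherry2}
  - {name: Alexa Fluor 594, like: mCherry2}
  - {name: PE-CF594, like: mCherry2}
  - {name: Dylight 594, like: mCherry2}
  - {name: APC, like: E2-Crimson}
  - {name: Alexa Fluor 647, like: E2-Crimson}
  - {name: Cy5, like: E2-Crimson}
  - {name: Sytox Red, like: E2-Crimson}
  - {name: Dylight 649, like: E2-Crimson}
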